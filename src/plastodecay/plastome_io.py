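"""Plastome records, quadripartite structure, GC and junction reports.

A plastome is a circular molecule with the canonical quadripartite
layout LSC - IRb - SSC - IRa (two identical inverted-repeat copies
separated by the large and small single-copy regions).  Internally the
sequence is stored linearized, by convention starting inside the LSC;
coordinates are 0-based half-open throughout, and features wrapping the
origin are split into two intervals and flagged.  GenBank's 1-based
inclusive convention is converted at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _seedextend
from .intervals import Interval, merge

TROPHIC_CLASSES = ("AP", "CP", "MP", "HP")
GENE_CATEGORIES = ("PS", "HK", "ndh", "tRNA", "rRNA")
GENE_STATUSES = ("intact", "pseudogene", "lost", "unknown")

_PS_PREFIXES = ("psa", "psb", "pet", "atp", "rbc", "ccsA", "cemA", "pbf")


def infer_category(name: str) -> str:
    low = name.lower()
    if low.startswith("ndh"):
        return "ndh"
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if any(low.startswith(p.lower()) for p in _PS_PREFIXES):
        return "PS"
    return "HK"


@dataclass
class GeneFeature:
    name: str
    category: str = "HK"
    strand: str = "+"
    intervals: List[Interval] = field(default_factory=list)
    status: str = "unknown"
    wraps_origin: bool = False

    def __post_init__(self):
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.status not in GENE_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if not self.intervals and self.status != "lost":
            raise ValueError(f"feature {self.name}: empty intervals only allowed for lost genes")

    @property
    def span(self) -> Interval:
        return (min(a for a, _ in self.intervals), max(b for _, b in self.intervals))

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.intervals)


@dataclass
class PlastomeRecord:
    id: str
    sequence: str
    taxon: str = ""
    trophic_class: Optional[str] = None
    features: List[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.id}: non-ACGTN symbols in sequence: {sorted(bad)}")
        if self.trophic_class is not None and self.trophic_class not in TROPHIC_CLASSES:
            raise ValueError(f"trophic_class must be one of {TROPHIC_CLASSES}")
        n = len(self.sequence)
        for f in self.features:
            for a, b in f.intervals:
                if not (0 <= a < b <= n):
                    raise ValueError(f"{self.id}/{f.name}: interval ({a},{b}) outside [0,{n})")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: GeneFeature) -> str:
        parts = [self.sequence[a:b] for a, b in feat.intervals]
        seq = "".join(parts)
        if feat.strand == "-":
            seq = _seedextend.revcomp(seq)
        return seq


@dataclass
class QuadripartiteMap:
    lsc: List[Interval]
    ssc: List[Interval]
    ira: List[Interval]
    irb: List[Interval]
    ir_length: int
    nonredundant_length: int
    has_ir: bool
    identity: float = 1.0
    genome_length: int = 0


@dataclass
class RegionGC:
    region_gc: Dict[str, float]
    genome_gc: float
    region_ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)


# ----------------------------------------------------------------------
# I/O


def read_plastome(path: str, format: str = "fasta") -> PlastomeRecord:
    """Read a plastome from FASTA or a GenBank flat file.

    GenBank gene/CDS/tRNA/rRNA features are mapped to GeneFeature
    entries (1-based inclusive converted to 0-based half-open by the
    parser); a plain FASTA yields an empty feature list.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "genbank", "gb"):
        raise ValueError(f"format must be FASTA or GenBank, got {format!r}")
    try:
        rec = next(SeqIO.parse(path, "genbank" if fmt in ("genbank", "gb") else "fasta"))
    except StopIteration:
        raise ValueError(f"{path}: no records found") from None
    except Exception as exc:  # malformed file
        raise ValueError(f"{path}: parse error: {exc}") from exc
    features: List[GeneFeature] = []
    if fmt in ("genbank", "gb"):
        seen = set()
        for sf in rec.features:
            if sf.type not in ("gene", "CDS", "tRNA", "rRNA"):
                continue
            quals = sf.qualifiers
            name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
            key = (name, str(sf.location))
            if key in seen:
                continue
            seen.add(key)
            ivs = sorted((int(p.start), int(p.end)) for p in sf.location.parts)
            strand = "-" if (sf.location.strand or 1) < 0 else "+"
            if strand == "-":
                ivs = sorted(ivs)
            features.append(GeneFeature(name=name, category=infer_category(name), strand=strand, intervals=ivs))
    return PlastomeRecord(
        id=rec.id or rec.name,
        sequence=str(rec.seq),
        taxon=rec.annotations.get("organism", "") if fmt in ("genbank", "gb") else "",
        features=features,
    )


def write_fasta(record: PlastomeRecord, path: str) -> None:
    SeqIO.write([SeqRecord(Seq(record.sequence), id=record.id, description=record.taxon)], path, "fasta")


def write_gff3(record: PlastomeRecord, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {len(record)}\n")
        for f in record.features:
            attrs = f"ID={f.name};category={f.category};status={f.status}"
            if f.wraps_origin:
                attrs += ";wraps_origin=true"
            for a, b in f.intervals:
                fh.write(
                    f"{record.id}\tplastodecay\tgene\t{a + 1}\t{b}\t.\t{f.strand}\t.\t{attrs}\n"
                )


def read_gff3_features(path: str) -> List[GeneFeature]:
    feats: Dict[str, GeneFeature] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            start, end, strand, attrs = int(cols[3]) - 1, int(cols[4]), cols[6], cols[8]
            kv = dict(item.split("=", 1) for item in attrs.split(";") if "=" in item)
            name = kv.get("ID", kv.get("Name", f"feat{lineno}"))
            if name not in feats:
                feats[name] = GeneFeature(
                    name=name,
                    category=kv.get("category", infer_category(name)),
                    strand=strand if strand in "+-" else "+",
                    intervals=[(start, end)],
                    status=kv.get("status", "unknown"),
                    wraps_origin=kv.get("wraps_origin") == "true",
                )
                order.append(name)
            else:
                feats[name].intervals.append((start, end))
                feats[name].intervals.sort()
    return [feats[n] for n in order]


def load_plastome(fasta_path: str, gff3_path: Optional[str] = None, **kwargs) -> PlastomeRecord:
    rec = read_plastome(fasta_path, "fasta")
    if gff3_path is not None:
        rec = PlastomeRecord(
            id=rec.id, sequence=rec.sequence, features=read_gff3_features(gff3_path), **kwargs
        )
    return rec


# ----------------------------------------------------------------------
# Quadripartite structure


def detect_inverted_repeat(
    record: PlastomeRecord, min_len: int = 1000, min_identity: float = 0.99
) -> QuadripartiteMap:
    """Locate the inverted repeat as the longest disjoint reverse-complement pair.

    Word-seeded (k=21 exact words) self-comparison against the reverse
    complement, ungapped extension; ties on length break toward higher
    identity, then leftmost.  The SSC is the shorter single-copy
    segment between the two IR copies.
    """
    if min_len < 100:
        raise ValueError("min_len must be >= 100")
    if not (0.9 < min_identity <= 1.0):
        raise ValueError("min_identity must lie in (0.9, 1.0]")
    n = len(record)
    no_ir = QuadripartiteMap(
        lsc=[(0, n)], ssc=[], ira=[], irb=[], ir_length=0,
        nonredundant_length=n, has_ir=False, genome_length=n,
    )
    if n < 2 * min_len:
        import warnings

        warnings.warn(f"{record.id}: sequence shorter than 2*min_len; has_ir=False")
        return no_ir

    hits = _seedextend.local_matches(record.sequence, None, word_size=21, xdrop=200, min_score=42)
    best = None
    for h in hits:
        if h.orientation != "inverted" or h.length < min_len or h.identity < min_identity:
            continue
        a = (h.q_start, h.q_end)
        b = (h.s_start, h.s_end)
        if a > b:
            a, b = b, a
        if a[1] > b[0]:  # overlapping copies: not a quadripartite IR
            continue
        key = (h.length, h.identity, -a[0])
        if best is None or key > best[0]:
            best = (key, a, b, h.identity)
    if best is None:
        return no_ir

    _, a, b, ident = best
    ir_len = a[1] - a[0]
    inner = (a[1], b[0])
    inner_len = inner[1] - inner[0]
    outer_len = n - b[1] + a[0]
    if inner_len <= outer_len:
        # layout: LSC (wrapping origin) - IR - SSC - IR
        ssc = [inner] if inner_len else []
        lsc = [iv for iv in ((b[1], n), (0, a[0])) if iv[1] > iv[0]]
        irb, ira = [a], [b]  # copy downstream of LSC is IRb
    else:
        ssc_ivs = [iv for iv in ((b[1], n), (0, a[0])) if iv[1] > iv[0]]
        ssc = ssc_ivs
        lsc = [inner]
        irb, ira = [b], [a]
    return QuadripartiteMap(
        lsc=lsc, ssc=ssc, ira=ira, irb=irb, ir_length=ir_len,
        nonredundant_length=n - ir_len, has_ir=True, identity=ident, genome_length=n,
    )


def nonredundant_length(qmap: QuadripartiteMap) -> int:
    """Genome length with one IR copy retained (total length when no IR)."""
    if qmap.has_ir:
        return qmap.genome_length - qmap.ir_length
    return qmap.genome_length


def ir_reduced_sequence(record: PlastomeRecord, qmap: QuadripartiteMap) -> str:
    """Sequence with the IRa copy removed (single-IR genome for repeat/homology work)."""
    if not qmap.has_ir:
        return record.sequence
    (a0, a1) = qmap.ira[0]
    return record.sequence[:a0] + record.sequence[a1:]


# ----------------------------------------------------------------------
# GC content


def _gc_tally(seq: str) -> Tuple[int, int]:
    """(GC count, non-N base count) in one pass."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc, acgt


def gc_by_region(
    record: PlastomeRecord,
    regions: Dict[str, Sequence[Interval]],
    bootstrap: bool = False,
    window: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> RegionGC:
    """GC fraction per labelled region (N bases excluded from both tallies).

    With ``bootstrap=True`` a percentile 95% CI per region is computed
    by resampling fixed-size non-overlapping windows.
    """
    n = len(record)
    rng = np.random.default_rng(seed)
    region_gc: Dict[str, float] = {}
    region_ci: Dict[str, Tuple[float, float]] = {}
    for label, ivs in regions.items():
        gc = acgt = 0
        chunks: List[str] = []
        for a, b in ivs:
            if not (0 <= a <= b <= n):
                raise ValueError(f"region {label}: interval ({a},{b}) outside genome [0,{n})")
            g, t = _gc_tally(record.sequence[a:b])
            gc += g
            acgt += t
            chunks.append(record.sequence[a:b])
        region_gc[label] = gc / acgt if acgt else math.nan
        if bootstrap:
            seq = "".join(chunks)
            wins = [seq[k : k + window] for k in range(0, len(seq) - window + 1, window)]
            if len(wins) >= 2:
                vals = []
                tallies = [_gc_tally(w) for w in wins]
                for _ in range(n_boot):
                    idx = rng.integers(0, len(wins), len(wins))
                    g = sum(tallies[i][0] for i in idx)
                    t = sum(tallies[i][1] for i in idx)
                    vals.append(g / t if t else math.nan)
                region_ci[label] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    g, t = _gc_tally(record.sequence)
    return RegionGC(region_gc=region_gc, genome_gc=g / t if t else math.nan, region_ci=region_ci)


# ----------------------------------------------------------------------
# Junctions


@dataclass
class JunctionInfo:
    junction: str  # JLB | JSB | JSA | JLA
    position: int
    upstream: Optional[str]
    upstream_distance: Optional[int]
    downstream: Optional[str]
    downstream_distance: Optional[int]
    spanning: Optional[str] = None  # feature overlapping the junction, if any


def junction_report(record: PlastomeRecord, qmap: QuadripartiteMap) -> List[JunctionInfo]:
    """Nearest feature on each side of the four IR/single-copy junctions.

    JLB = LSC/IRb, JSB = IRb/SSC, JSA = SSC/IRa, JLA = IRa/LSC.  A
    feature spanning a junction is reported on both sides and flagged.
    """
    if not record.features:
        import warnings

        warnings.warn(f"{record.id}: no features; junction report empty")
        return []
    if not qmap.has_ir:
        return []
    (b0, b1) = qmap.irb[0]
    (a0, a1) = qmap.ira[0]
    positions = [("JLB", b0), ("JSB", b1), ("JSA", a0), ("JLA", a1 % qmap.genome_length)]
    out = []
    for name, pos in positions:
        up = dn = None
        up_d = dn_d = None
        spanning = None
        for f in record.features:
            s, e = f.span
            if s < pos < e:
                spanning = f.name
                up, up_d = f.name, 0
                dn, dn_d = f.name, 0
                break
        if spanning is None:
            for f in record.features:
                s, e = f.span
                if e <= pos and (up_d is None or pos - e < up_d):
                    up, up_d = f.name, pos - e
                if s >= pos and (dn_d is None or s - pos < dn_d):
                    dn, dn_d = f.name, s - pos
        out.append(JunctionInfo(name, pos, up, up_d, dn, dn_d, spanning))
    return out


def structure_report(
    records: Iterable[PlastomeRecord], min_ir_len: int = 1000, min_ir_identity: float = 0.99
):
    """Per-genome structure table: lengths, IR size, non-redundant length, GC."""
    import pandas as pd

    rows = []
    for rec in records:
        qmap = detect_inverted_repeat(rec, min_ir_len, min_ir_identity)
        regions = {
            "LSC": qmap.lsc,
            "SSC": qmap.ssc,
            "IR": qmap.ira + qmap.irb,
        }
        gc = gc_by_region(rec, {k: v for k, v in regions.items() if v})
        rows.append(
            {
                "id": rec.id,
                "taxon": rec.taxon,
                "trophic_class": rec.trophic_class,
                "length": len(rec),
                "has_ir": qmap.has_ir,
                "ir_length": qmap.ir_length,
                "nonredundant_length": nonredundant_length(qmap),
                "gc_genome": gc.genome_gc,
                "gc_lsc": gc.region_gc.get("LSC", math.nan),
                "gc_ssc": gc.region_gc.get("SSC", math.nan),
                "gc_ir": gc.region_gc.get("IR", math.nan),
            }
        )
    return pd.DataFrame(rows)
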