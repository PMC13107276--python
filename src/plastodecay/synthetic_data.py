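"""Synthetic plastomes, codon alignments, counts and pileups with planted truth.

Every generator is deterministic under a fixed seed and emits both the
data object and a truth record, so each pipeline stage can be tested
for recovery without any external data.  Defaults emulate a typical
quadripartite plastome: 84 kb LSC + 25 kb IR + 18 kb SSC (~152 kb
total), overall GC near 0.37, a gene roster with photosynthesis (PS),
housekeeping (HK) and ndh categories including the canonical
ndhJ-ndhK-ndhC (LSC) and ndhH-ndhA-ndhI-ndhG-ndhE-psaC-ndhD (SSC)
clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _seedextend
from .codon import CODONS, STOP_CODONS
from .plastome_io import GeneFeature, PlastomeRecord, infer_category
from .selection_models import CodonAlignment, SpectralQ, TreeModel, codon_rate_matrix

_SENSE = [c for c in CODONS if c != "ATG"]


# ----------------------------------------------------------------------
# Configuration


@dataclass
class RosterGene:
    name: str
    n_codons: int
    region: str  # LSC | SSC | IR
    strand: str = "+"

    @property
    def category(self) -> str:
        return infer_category(self.name)


def default_roster() -> List[RosterGene]:
    """A realistic plastome gene roster (protein genes only; lengths in codons)."""
    lsc_ps = [
        ("psbA", 353), ("psbB", 508), ("psbC", 473), ("psbD", 353), ("psbI", 36),
        ("psaA", 750), ("psaB", 734), ("rbcL", 477), ("petA", 320), ("petB", 215),
        ("atpA", 507), ("atpB", 498), ("atpE", 133), ("atpF", 184), ("atpH", 81),
        ("atpI", 247),
    ]
    lsc_hk = [
        ("rpoA", 337), ("rpoB", 1070), ("rpoC1", 680), ("rpoC2", 1392),
        ("rps2", 236), ("rps3", 218), ("rps4", 201), ("rps8", 134), ("rps11", 138),
        ("rps14", 100), ("rps18", 101), ("rps19", 92), ("rpl2", 274), ("rpl14", 122),
        ("rpl16", 135), ("rpl20", 128), ("rpl22", 155), ("rpl33", 66), ("rpl36", 37),
        ("matK", 509), ("clpP", 196), ("accD", 488), ("cemA", 229), ("ccsA", 319),
        ("infA", 77),
    ]
    lsc_ndh = [("ndhJ", 158), ("ndhK", 225), ("ndhC", 120), ("ndhB", 510)]
    ssc = [
        ("ndhF", 740), ("rpl32", 55),
        ("ndhH", 393), ("ndhA", 364), ("ndhI", 166), ("ndhG", 176), ("ndhE", 101),
        ("psaC", 81), ("ndhD", 509), ("rps15", 90), ("ycf1", 1800),
    ]
    roster = [RosterGene(n, c, "LSC") for n, c in lsc_ps + lsc_hk + lsc_ndh]
    roster += [RosterGene(n, c, "SSC") for n, c in ssc]
    roster += [RosterGene("rps7", 155, "IR"), RosterGene("rpl23", 93, "IR")]
    return roster


def compact_roster() -> List[RosterGene]:
    """Small roster for fast tests: all 11 ndh genes plus a PS/HK core."""
    genes = [
        RosterGene("psbA", 120, "LSC"), RosterGene("rbcL", 140, "LSC"),
        RosterGene("atpA", 110, "LSC"), RosterGene("rpoA", 130, "LSC", "-"),
        RosterGene("rps19", 92, "LSC"), RosterGene("rpl22", 100, "LSC"),
        RosterGene("matK", 120, "LSC"),
        RosterGene("ndhJ", 80, "LSC"), RosterGene("ndhK", 85, "LSC"),
        RosterGene("ndhC", 60, "LSC"), RosterGene("ndhB", 150, "LSC"),
        RosterGene("ndhF", 160, "SSC"), RosterGene("ndhH", 120, "SSC"),
        RosterGene("ndhA", 110, "SSC"), RosterGene("ndhI", 70, "SSC"),
        RosterGene("ndhG", 70, "SSC"), RosterGene("ndhE", 55, "SSC"),
        RosterGene("psaC", 60, "SSC"), RosterGene("ndhD", 130, "SSC"),
        RosterGene("rps15", 60, "SSC"),
    ]
    return genes


@dataclass
class GeneratorConfig:
    lsc_length: int = 84_000
    ir_length: int = 25_000
    ssc_length: int = 18_000
    gc: float = 0.37
    roster: List[RosterGene] = field(default_factory=default_roster)
    #: gene -> ("truncate", coverage) | ("delete",) | ("premature_stop", frac)
    degradation: Dict[str, Tuple] = field(default_factory=dict)
    #: list of (region, length, gc) foreign insertions
    insertions: List[Tuple[str, int, float]] = field(default_factory=list)
    #: list of (length, inverted) planted intragenomic duplications in the LSC
    repeats: List[Tuple[int, bool]] = field(default_factory=list)
    #: length of an SSC block to invert (0 = none)
    ssc_inversion: int = 0


def compact_config(**kwargs) -> GeneratorConfig:
    defaults = dict(
        lsc_length=13_000, ir_length=3_000, ssc_length=6_000,
        roster=compact_roster(),
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@dataclass
class SyntheticTruth:
    seed: int
    gene_status: Dict[str, str] = field(default_factory=dict)
    planted_coverage: Dict[str, float] = field(default_factory=dict)
    ref_cds: Dict[str, str] = field(default_factory=dict)
    ir_intervals: List[Tuple[int, int]] = field(default_factory=list)
    insertion_intervals: List[Tuple[int, int]] = field(default_factory=list)
    repeat_intervals: List[Tuple[int, int]] = field(default_factory=list)
    inversion_interval: Optional[Tuple[int, int]] = None
    omega_fg: Optional[float] = None
    omega_bg: Optional[float] = None
    editing_sites: List[Tuple[int, float]] = field(default_factory=list)
    fpkm: Optional[pd.Series] = None


# ----------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + TAA; no internal stops or internal ATG frame resets."""
    body = [str(_SENSE[i]) for i in rng.integers(0, len(_SENSE), max(n_codons - 2, 0))]
    return "ATG" + "".join(body) + "TAA"


def nonhomologous_seq(
    rng: np.random.Generator, length: int, host: str, w: int = 12,
    gc: float = 0.6, max_iter: int = 500,
) -> str:
    """Random sequence sharing no exact ``w``-mer with ``host`` (either strand).

    Starts from a random draw and iteratively mutates one base inside
    every window still shared with the host; at w = 12 the expected
    number of chance collisions is small and the repair converges in a
    few passes.  Such a fragment cannot seed an alignment anchor of
    useful length against the host.
    """
    host_words = {host[i : i + w] for i in range(len(host) - w + 1)}
    rc = _seedextend.revcomp(host)
    host_words |= {rc[i : i + w] for i in range(len(rc) - w + 1)}
    seq = list(_random_seq(rng, length, gc))
    for _ in range(max_iter):
        bad = [
            i for i in range(length - w + 1) if "".join(seq[i : i + w]) in host_words
        ]
        if not bad:
            return "".join(seq)
        for i in bad:
            j = i + int(rng.integers(0, w))
            seq[j] = "ACGT"[int(rng.integers(0, 4))]
    raise RuntimeError("could not construct a non-homologous fragment")


# ----------------------------------------------------------------------
# Plastome generation


def make_plastome(
    config: GeneratorConfig, seed: int = 0, record_id: str = "synth",
    taxon: str = "Synthetica plantaris", trophic_class: str = "AP",
) -> Tuple[PlastomeRecord, SyntheticTruth]:
    """Quadripartite plastome with planted gene models and degradations.

    Layout: LSC - IRb - SSC - IRa (IRa = reverse complement of IRb).
    The truth record keeps the full-length reference CDS of every
    roster gene (the "tobacco-like" reference), the planted status and
    the intended coverage fraction of truncated genes.
    """
    rng = np.random.default_rng(seed)
    # independent child streams per region (plus one for structural
    # edits): genomes generated from one seed under different region
    # budgets or degradation plans stay homologous everywhere else
    lsc_rng, ssc_rng, ir_rng, edit_rng = rng.spawn(4)
    region_rngs = {"LSC": lsc_rng, "SSC": ssc_rng, "IR": ir_rng}
    truth = SyntheticTruth(seed=seed)

    region_genes: Dict[str, List[RosterGene]] = {"LSC": [], "SSC": [], "IR": []}
    for g in config.roster:
        region_genes[g.region].append(g)

    region_seqs: Dict[str, str] = {}
    region_feats: Dict[str, List[GeneFeature]] = {}
    region_lengths = {
        "LSC": config.lsc_length, "SSC": config.ssc_length, "IR": config.ir_length,
    }

    for region, genes in region_genes.items():
        rng = region_rngs[region]
        pieces: List[str] = []
        feats: List[GeneFeature] = []
        pos = 0
        budget = region_lengths[region]
        gene_total = 0
        for g in genes:
            ref = _random_orf(rng, g.n_codons)
            truth.ref_cds[g.name] = ref
            plan = config.degradation.get(g.name)
            status = "intact"
            placed: Optional[str] = ref
            if plan is not None:
                kind = plan[0]
                if kind == "delete":
                    status, placed = "lost", None
                elif kind == "truncate":
                    cov = float(plan[1])
                    keep = max(2, int(round(cov * g.n_codons)) - 1)
                    placed = ref[: 3 * keep] + "TAA"
                    status = "intact" if (3 * keep + 3) / len(ref) >= 0.70 else "pseudogene"
                    truth.planted_coverage[g.name] = (3 * keep + 3) / len(ref)
                elif kind == "premature_stop":
                    frac = float(plan[1])
                    k = max(1, int(frac * g.n_codons))
                    placed = ref[: 3 * k] + "TAA" + ref[3 * k + 3 :]
                    status = "pseudogene" if (3 * k + 3) / len(ref) < 0.70 else "intact"
                    truth.planted_coverage[g.name] = (3 * k + 3) / len(ref)
                else:
                    raise ValueError(f"unknown degradation kind {kind!r}")
            truth.gene_status[g.name] = status
            # spacer drawn unconditionally: genomes generated from one
            # seed under different degradation plans stay base-for-base
            # homologous outside the planted edits
            spacer_len = int(rng.integers(40, 120))
            spacer = _random_seq(rng, spacer_len, config.gc)
            if placed is None:
                pieces.append(spacer)
                pos += spacer_len
                gene_total += spacer_len
                continue
            insert = placed if g.strand == "+" else _seedextend.revcomp(placed)
            pieces.append(spacer)
            pos += spacer_len
            feats.append(
                GeneFeature(
                    name=g.name, category=g.category, strand=g.strand,
                    intervals=[(pos, pos + len(insert))], status=status,
                )
            )
            pieces.append(insert)
            pos += len(insert)
            gene_total += len(insert) + spacer_len
        if gene_total > budget:
            raise ValueError(
                f"plan overflow: {region} genes+spacers need {gene_total} bp "
                f"but region is {budget} bp"
            )
        pieces.append(_random_seq(rng, budget - pos, config.gc))
        region_seqs[region] = "".join(pieces)
        region_feats[region] = feats

    lsc, ssc, irb = region_seqs["LSC"], region_seqs["SSC"], region_seqs["IR"]
    rng = edit_rng

    # planted intragenomic duplications inside the LSC tail
    for length, inverted in config.repeats:
        src_start = int(rng.integers(0, len(lsc) - length))
        block = lsc[src_start : src_start + length]
        if inverted:
            block = _seedextend.revcomp(block)
        lsc = lsc + block
        truth.repeat_intervals.append((len(lsc) - length, len(lsc)))

    # foreign insertions with distinct GC, constructed non-homologous
    local_insertions: List[Tuple[str, int, int]] = []
    for region, length, gc in config.insertions:
        host = {"LSC": lsc, "SSC": ssc}[region]
        foreign = nonhomologous_seq(rng, length, lsc + irb + ssc, gc=gc)
        at = len(host)
        host = host + foreign
        if region == "LSC":
            lsc = host
        else:
            ssc = host
        local_insertions.append((region, at, at + length))

    if config.ssc_inversion:
        L = min(config.ssc_inversion, len(ssc) // 2)
        a = int(rng.integers(0, len(ssc) - L))
        ssc = ssc[:a] + _seedextend.revcomp(ssc[a : a + L]) + ssc[a + L :]
        truth.inversion_interval = (a, a + L)

    ira = _seedextend.revcomp(irb)
    genome = lsc + irb + ssc + ira
    off_irb = len(lsc)
    off_ssc = off_irb + len(irb)
    off_ira = off_ssc + len(ssc)
    truth.ir_intervals = [(off_irb, off_ssc), (off_ira, len(genome))]

    features: List[GeneFeature] = []
    for f in region_feats["LSC"]:
        features.append(f)
    for f in region_feats["IR"]:
        features.append(
            GeneFeature(f.name, f.category, f.strand,
                        [(a + off_irb, b + off_irb) for a, b in f.intervals], f.status)
        )
    for f in region_feats["SSC"]:
        features.append(
            GeneFeature(f.name, f.category, f.strand,
                        [(a + off_ssc, b + off_ssc) for a, b in f.intervals], f.status)
        )
    region_offsets = {"LSC": 0, "SSC": off_ssc}
    truth.insertion_intervals = [
        (region_offsets[r] + a, region_offsets[r] + b) for r, a, b in local_insertions
    ]
    if truth.inversion_interval is not None:
        a, b = truth.inversion_interval
        truth.inversion_interval = (a + off_ssc, b + off_ssc)
    truth.repeat_intervals = [(a, b) for a, b in truth.repeat_intervals]
    rec = PlastomeRecord(
        id=record_id, sequence=genome, taxon=taxon,
        trophic_class=trophic_class, features=features,
    )
    return rec, truth


# ----------------------------------------------------------------------
# Codon alignment simulation


def simulate_codon_alignment(
    tree: TreeModel,
    pi: np.ndarray,
    n_codons: int,
    seed: int = 0,
    omega_fg: float = 0.5,
    omega_bg: float = 0.5,
    kappa: float = 2.0,
    site_classes: Optional[Sequence[Tuple[float, float, float]]] = None,
) -> Tuple[CodonAlignment, SyntheticTruth]:
    """Evolve codons down the tree under branch-specific MG94.

    Root codons are drawn from ``pi``; each branch applies the
    transition matrix of its omega class (foreground branches use
    ``omega_fg``).  ``site_classes`` optionally lists
    (proportion, fg_omega, bg_omega) triples for branch-site style
    simulation; proportions must sum to 1 and override omega_fg/bg.
    Stop codons cannot arise: the state space is the 61 sense codons.
    """
    rng = np.random.default_rng(seed)
    pi = np.asarray(pi, dtype=float)
    if site_classes is None:
        site_classes = [(1.0, omega_fg, omega_bg)]
    props = np.array([c[0] for c in site_classes], dtype=float)
    if not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("site class proportions must sum to 1")
    class_of_site = rng.choice(len(site_classes), size=n_codons, p=props)

    # transition matrices per (class, node)
    specs: Dict[float, SpectralQ] = {}
    for _, wf, wb in site_classes:
        for w in (wf, wb):
            if w not in specs:
                specs[w] = SpectralQ(codon_rate_matrix(pi, w, kappa), pi)

    states = {tree.root: rng.choice(61, size=n_codons, p=pi / pi.sum())}
    for v in reversed(tree.postorder):  # preorder
        if tree.parent[v] < 0:
            continue
        parent_states = states[tree.parent[v]]
        child = np.empty(n_codons, dtype=np.int64)
        for c_idx, (_, wf, wb) in enumerate(site_classes):
            mask = class_of_site == c_idx
            if not mask.any():
                continue
            w = wf if tree.fg[v] else wb
            P = specs[w].P(tree.lengths[v])
            P = P / P.sum(axis=1, keepdims=True)
            ps = parent_states[mask]
            out = np.empty(ps.shape, dtype=np.int64)
            for s in np.unique(ps):
                sel = ps == s
                out[sel] = rng.choice(61, size=int(sel.sum()), p=P[s])
            sub = child[mask]
            sub[:] = out
            child[mask] = sub
        states[v] = child

    seqs = {t: "".join(CODONS[i] for i in states[tree.leaf_index[t]]) for t in tree.taxa}
    aln = CodonAlignment.from_sequences(seqs)
    truth = SyntheticTruth(
        seed=seed,
        omega_fg=site_classes[0][1] if len(site_classes) == 1 else None,
        omega_bg=site_classes[0][2] if len(site_classes) == 1 else None,
    )
    return aln, truth


# ----------------------------------------------------------------------
# Fragment counts


def simulate_counts(
    truth_fpkm: pd.Series,
    lengths: pd.Series,
    total_fragments: int,
    dispersion: float = 0.1,
    seed: int = 0,
    strands: Optional[pd.Series] = None,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Negative-binomial fragment counts whose expectation inverts the FPKM formula.

    Expected count = FPKM * total * length_kb / 1e6; ``dispersion`` is
    the NB over-dispersion (variance = mu + dispersion * mu^2), with 0
    giving Poisson counts.
    """
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    rng = np.random.default_rng(seed)
    mu = truth_fpkm * total_fragments * (lengths / 1000.0) / 1e6
    if (mu < 0).any():
        raise ValueError("FPKM values must be non-negative")
    if dispersion <= 0:
        counts = rng.poisson(mu.values)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu.values)
        counts = np.where(mu.values > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    df = pd.DataFrame(
        {
            "feature": truth_fpkm.index,
            "length": lengths.reindex(truth_fpkm.index).values,
            "strand": (strands.reindex(truth_fpkm.index).values if strands is not None else "+"),
            "count": counts,
        }
    ).set_index("feature")
    truth = SyntheticTruth(seed=seed, fpkm=truth_fpkm.copy())
    return df, truth


# ----------------------------------------------------------------------
# Pileups


def simulate_pileup(
    genome: str,
    site_plan: Sequence[Tuple[int, float]] = (),
    mean_coverage: float = 100.0,
    error_rate: float = 0.001,
    seed: int = 0,
    plus_fraction: Mapping[int, float] | None = None,
    positions: Optional[Sequence[int]] = None,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Strand-split pileup with planted C-to-U editing sites.

    ``site_plan`` lists (position, efficiency); each position must hold
    C (edited to T) or G (edited to A, antisense editing) in the
    genome.  ``plus_fraction`` optionally forces the fraction of
    variant reads on the plus strand per site, to exercise the
    strand-bias filter.  Non-site positions carry uniform errors at
    ``error_rate`` per base.
    """
    rng = np.random.default_rng(seed)
    n = len(genome)
    pos = np.asarray(positions if positions is not None else np.arange(n), dtype=int)
    refs = np.array(list(genome))[pos]
    for p, _ in site_plan:
        if genome[p] not in "CG":
            raise ValueError(f"editing site at {p} is {genome[p]!r}, expected C or G")

    cov = rng.poisson(mean_coverage, len(pos)).astype(int)
    cov_plus = rng.binomial(cov, 0.5)
    cov_minus = cov - cov_plus
    bases = ["A", "C", "G", "T"]
    base_idx = {b: i for i, b in enumerate(bases)}

    counts = {s: np.zeros((len(pos), 4), dtype=int) for s in "+-"}
    for strand, c in (("+", cov_plus), ("-", cov_minus)):
        errs = rng.binomial(c, error_rate)
        # distribute errors uniformly over the three alternatives
        e1 = rng.binomial(errs, 1 / 3)
        e2 = rng.binomial(errs - e1, 1 / 2)
        e3 = errs - e1 - e2
        alt_err = np.stack([e1, e2, e3], axis=1)
        for i, b in enumerate(bases):
            mask = refs == b
            alts = [x for x in bases if x != b]
            counts[strand][mask, base_idx[b]] = c[mask] - errs[mask]
            for k, ab in enumerate(alts):
                counts[strand][mask, base_idx[ab]] += alt_err[mask, k]

    pos_index = {int(p): i for i, p in enumerate(pos)}
    planted: List[Tuple[int, float]] = []
    for p, eff in site_plan:
        if int(p) not in pos_index:
            continue
        i = pos_index[int(p)]
        ref = genome[p]
        alt = "T" if ref == "C" else "A"
        v = rng.binomial(cov[i], eff)
        frac = 0.5 if plus_fraction is None else plus_fraction.get(int(p), 0.5)
        vp = min(int(rng.binomial(v, frac)), int(cov_plus[i]))
        vm = min(v - vp, int(cov_minus[i]))
        counts["+"][i, base_idx[alt]] = vp
        counts["+"][i, base_idx[ref]] = cov_plus[i] - vp
        counts["-"][i, base_idx[alt]] = vm
        counts["-"][i, base_idx[ref]] = cov_minus[i] - vm
        planted.append((int(p), eff))

    frames = []
    for strand in "+-":
        frames.append(
            pd.DataFrame(
                {
                    "pos": pos, "strand": strand, "refbase": refs,
                    "A": counts[strand][:, 0], "C": counts[strand][:, 1],
                    "G": counts[strand][:, 2], "T": counts[strand][:, 3],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True).sort_values(["pos", "strand"], kind="stable")
    truth = SyntheticTruth(seed=seed, editing_sites=planted)
    return df.reset_index(drop=True), truth
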