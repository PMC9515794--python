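"""Chromosome-level UPD metrics, classification, and segmental window scan.

The screen rests on two per-chromosome quantities computed from a filtered
trio genotype table:

* **uniparental skew** — at *informative* sites (one parent homozygous
  reference, the other homozygous alternate; the biparental expectation for
  the child is heterozygous, "AB"), the percentage of proband genotypes
  identical to each parent's genotype.  The skew is the larger of the two.
* **heterozygosity** — percentage of heterozygous proband calls across all
  proband non-missing sites of the chromosome.

Whole-chromosome isodisomy (UPiD) shows >90% skew with <10% heterozygosity
(one duplicated homolog renders the chromosome homozygous); heterodisomy
(UPhD) shows >90% skew with >30% heterozygosity (both homologs of one parent
retained).  Segmental events are found by anchoring 5 Mb windows at
Mendelian-error sites, keeping error-dense low-heterozygosity windows,
merging overlaps, and separating deletions from true segmental UPD by the
region's read-depth ratio to the genome-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan, nan

import numpy as np
import pandas as pd

from .genotype_store import HET, HOM_ALT, HOM_REF, MISSING, TrioGenotypes, normalize_chrom

MATCH_NOT_APPLICABLE = "not_applicable"
MATCH_MOTHER = "mother"
MATCH_FATHER = "father"
MATCH_BIPARENTAL_HET = "biparental_het"


@dataclass(frozen=True)
class SiteClass:
    informative: bool
    mendelian_error: bool
    proband_match: str


def _can_transmit_ref(gt: np.ndarray) -> np.ndarray:
    return (gt == HOM_REF) | (gt == HET)


def _can_transmit_alt(gt: np.ndarray) -> np.ndarray:
    return (gt == HOM_ALT) | (gt == HET)


def _site_flags(gm: np.ndarray, gf: np.ndarray, gp: np.ndarray):
    """Vectorized per-site classification; returns (informative, merror, match_code).

    match_code: 0 n/a, 1 mother, 2 father, 3 biparental het.  Defined only at
    informative sites with a non-missing proband genotype.
    """
    m_ok = gm != MISSING
    f_ok = gf != MISSING
    p_ok = gp != MISSING
    all_ok = m_ok & f_ok & p_ok

    consistent = np.zeros(gm.shape, dtype=bool)
    consistent |= (gp == HOM_REF) & _can_transmit_ref(gm) & _can_transmit_ref(gf)
    consistent |= (gp == HOM_ALT) & _can_transmit_alt(gm) & _can_transmit_alt(gf)
    consistent |= (gp == HET) & (
        (_can_transmit_ref(gm) & _can_transmit_alt(gf))
        | (_can_transmit_alt(gm) & _can_transmit_ref(gf))
    )
    merror = all_ok & ~consistent

    informative = m_ok & f_ok & (
        ((gm == HOM_REF) & (gf == HOM_ALT)) | ((gm == HOM_ALT) & (gf == HOM_REF))
    )
    match = np.zeros(gm.shape, dtype=np.int8)
    at = informative & p_ok
    match[at & (gp == HET)] = 3
    match[at & (gp == gm)] = 1
    match[at & (gp == gf)] = 2
    return informative, merror, match


def classify_site(g_mother: int, g_father: int, g_proband: int) -> SiteClass:
    """Classify one genotype triple.

    A Mendelian error means no choice of one transmitted allele per parent
    can produce the proband genotype; a missing genotype anywhere makes the
    site neither an error nor informative for matching that sample.
    """
    gm = np.array([g_mother])
    gf = np.array([g_father])
    gp = np.array([g_proband])
    informative, merror, match = _site_flags(gm, gf, gp)
    code = {0: MATCH_NOT_APPLICABLE, 1: MATCH_MOTHER, 2: MATCH_FATHER, 3: MATCH_BIPARENTAL_HET}
    return SiteClass(
        informative=bool(informative[0]),
        mendelian_error=bool(merror[0]),
        proband_match=code[int(match[0])],
    )


@dataclass
class ChromosomeStats:
    """The two screening metrics plus direction percentages for one chromosome.

    Percentages are ``nan`` (undefined, not zero) when their denominator is
    empty.  ``n_informative`` counts informative sites with a non-missing
    proband genotype — the denominator for pct_ab and the match percentages.
    """

    chromosome: str
    n_nonmissing: int
    n_het: int
    n_informative: int
    n_ab: int
    n_match_mother: int
    n_match_father: int
    n_mendelian_errors: int

    @property
    def pct_het(self) -> float:
        return 100.0 * self.n_het / self.n_nonmissing if self.n_nonmissing else nan

    @property
    def pct_ab(self) -> float:
        return 100.0 * self.n_ab / self.n_informative if self.n_informative else nan

    @property
    def pct_match_mother(self) -> float:
        return 100.0 * self.n_match_mother / self.n_informative if self.n_informative else nan

    @property
    def pct_match_father(self) -> float:
        return 100.0 * self.n_match_father / self.n_informative if self.n_informative else nan

    @property
    def skew(self) -> float:
        if self.n_informative == 0:
            return nan
        return max(self.pct_match_mother, self.pct_match_father)

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "n_nonmissing": self.n_nonmissing,
            "n_het": self.n_het,
            "n_informative": self.n_informative,
            "n_ab": self.n_ab,
            "n_match_mother": self.n_match_mother,
            "n_match_father": self.n_match_father,
            "n_mendelian_errors": self.n_mendelian_errors,
            "pct_het": self.pct_het,
            "pct_ab": self.pct_ab,
            "pct_match_mother": self.pct_match_mother,
            "pct_match_father": self.pct_match_father,
            "skew": self.skew,
        }


@dataclass(frozen=True)
class ClassifyThresholds:
    """Whole-chromosome call thresholds (shipped values are the screen's).

    ``skew_min``: minimum uniparental skew (%) for any disomy call;
    ``upid_het_max`` / ``uphd_het_min``: heterozygosity bounds (%) separating
    isodisomy from heterodisomy; ``min_informative`` / ``min_nonmissing``:
    site-count floors below which percentages are too unstable to call;
    ``het_excess_pct``: advisory flag level for trisomy-like heterozygosity
    excess (clearly above the ~50% Hardy–Weinberg ceiling at MAF >= 0.4).
    """

    skew_min: float = 90.0
    upid_het_max: float = 10.0
    uphd_het_min: float = 30.0
    min_informative: int = 200
    min_nonmissing: int = 1000
    het_excess_pct: float = 60.0

    def __post_init__(self) -> None:
        if not self.upid_het_max < self.uphd_het_min:
            raise ValueError("upid_het_max must be < uphd_het_min")
        if not 50.0 < self.skew_min <= 100.0:
            raise ValueError("skew_min must be in (50, 100]")


CALL_NONE = "none"
CALL_UPID = "upid"
CALL_UPHD = "uphd"
CALL_AMBIGUOUS = "ambiguous_skewed"
CALL_INSUFFICIENT = "insufficient_data"
CALL_HET_EXCESS = "het_excess_flag"

WHOLE_CHROMOSOME_CALLS = (CALL_UPID, CALL_UPHD, CALL_AMBIGUOUS)


@dataclass
class ChromosomeCall:
    chromosome: str
    call: str
    parent: str  # mother | father | not_applicable
    stats: ChromosomeStats

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "call": self.call,
            "parent": self.parent,
            "stats": self.stats.to_dict(),
        }


def chromosome_stats(trio: TrioGenotypes, chromosome: str) -> ChromosomeStats:
    """Compute the two screening metrics for one chromosome.

    Heterozygosity runs over proband non-missing sites; AB and parent-match
    percentages over informative sites with a non-missing proband genotype.
    """
    chrom = normalize_chrom(chromosome)
    sub = trio.subset(chrom)
    gm = sub["gt_mother"].to_numpy()
    gf = sub["gt_father"].to_numpy()
    gp = sub["gt_proband"].to_numpy()
    informative, merror, match = _site_flags(gm, gf, gp)
    nonmissing = gp != MISSING
    return ChromosomeStats(
        chromosome=chrom,
        n_nonmissing=int(nonmissing.sum()),
        n_het=int((gp == HET).sum()),
        n_informative=int((informative & nonmissing).sum()),
        n_ab=int((match == 3).sum()),
        n_match_mother=int((match == 1).sum()),
        n_match_father=int((match == 2).sum()),
        n_mendelian_errors=int(merror.sum()),
    )


def disomy_direction(stats: ChromosomeStats):
    """Parent of origin: argmax of the two match percentages.

    Returns ``(parent, percentage)``; an exact tie reports ``undetermined``.
    """
    if stats.n_informative == 0:
        raise ValueError(f"no informative sites on chromosome {stats.chromosome}")
    pm, pf = stats.pct_match_mother, stats.pct_match_father
    if pm == pf:
        return "undetermined", pm
    return (MATCH_MOTHER, pm) if pm > pf else (MATCH_FATHER, pf)


def classify_chromosome(
    stats: ChromosomeStats,
    thresholds: ClassifyThresholds | None = None,
    proband_sex: str = "female",
) -> ChromosomeCall:
    """Whole-chromosome call from the two metrics (pure function of stats).

    Skew above ``skew_min`` with heterozygosity below ``upid_het_max`` is
    isodisomy; above ``uphd_het_min``, heterodisomy; in between,
    ``ambiguous_skewed`` (the screen defines only the two extremes).
    Without skew, heterozygosity above ``het_excess_pct`` raises an advisory
    trisomy-like flag.  The X chromosome is never called in males.
    """
    if thresholds is None:
        thresholds = ClassifyThresholds()
    chrom = stats.chromosome

    def _call(kind: str, parent: str = MATCH_NOT_APPLICABLE) -> ChromosomeCall:
        return ChromosomeCall(chromosome=chrom, call=kind, parent=parent, stats=stats)

    if chrom == "X" and proband_sex == "male":
        return _call(CALL_INSUFFICIENT)
    if (
        stats.n_nonmissing < thresholds.min_nonmissing
        or stats.n_informative < thresholds.min_informative
    ):
        return _call(CALL_INSUFFICIENT)

    het = stats.pct_het
    if stats.skew > thresholds.skew_min:
        parent, _ = disomy_direction(stats)
        if het < thresholds.upid_het_max:
            return _call(CALL_UPID, parent)
        if het > thresholds.uphd_het_min:
            return _call(CALL_UPHD, parent)
        return _call(CALL_AMBIGUOUS, parent)
    if het > thresholds.het_excess_pct:
        return _call(CALL_HET_EXCESS)
    return _call(CALL_NONE)


# ---------------------------------------------------------------------------
# segmental scan

@dataclass(frozen=True)
class Window:
    """One retained error-anchored window, [start, end) in 1-based coordinates."""

    start: int
    end: int
    n_errors: int
    n_informative: int
    pct_het_informative: float


def scan_partial(
    trio: TrioGenotypes,
    chromosome: str,
    window_size: int = 5_000_000,
    min_errors: int = 50,
    het_max_pct: float = 10.0,
) -> list:
    """Scan one chromosome for segmental UPD/deletion candidate windows.

    Every Mendelian-error site at position ``p`` anchors the window
    ``[p, p + window_size)``.  A window is retained iff it contains at least
    ``min_errors`` Mendelian-error sites and the proband heterozygosity at
    its informative sites does not exceed ``het_max_pct`` (a window with no
    informative sites cannot be removed on heterozygosity).
    """
    sub = trio.subset(chromosome)
    pos = sub["pos"].to_numpy(np.int64)
    gm = sub["gt_mother"].to_numpy()
    gf = sub["gt_father"].to_numpy()
    gp = sub["gt_proband"].to_numpy()
    informative, merror, match = _site_flags(gm, gf, gp)
    het_inf = match == 3  # proband het at an informative site
    inf_called = informative & (gp != MISSING)

    cum_err = np.concatenate([[0], np.cumsum(merror)])
    cum_inf = np.concatenate([[0], np.cumsum(inf_called)])
    cum_het = np.concatenate([[0], np.cumsum(het_inf)])

    out = []
    for i in np.flatnonzero(merror):
        start = int(pos[i])
        end = start + window_size
        j = int(np.searchsorted(pos, end, side="left"))
        n_err = int(cum_err[j] - cum_err[i])
        if n_err < min_errors:
            continue
        n_inf = int(cum_inf[j] - cum_inf[i])
        n_het = int(cum_het[j] - cum_het[i])
        pct = 100.0 * n_het / n_inf if n_inf else 0.0
        if n_inf and pct > het_max_pct:
            continue
        out.append(Window(start, end, n_err, n_inf, pct if n_inf else nan))
    return out


def merge_windows(windows: list) -> list:
    """Merge half-open intervals into the minimal disjoint sorted set.

    Accepts :class:`Window` objects or ``(start, end)`` pairs; returns
    ``(start, end)`` tuples.  Idempotent; adjacent intervals merge.
    """
    ivs = sorted(
        (w.start, w.end) if isinstance(w, Window) else (int(w[0]), int(w[1]))
        for w in windows
    )
    merged: list = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [tuple(iv) for iv in merged]


RESOLUTION_PARTIAL_UPD = "partial_upd"
RESOLUTION_DELETION = "deletion"


@dataclass
class CandidateRegion:
    """A merged segmental candidate resolved to partial UPD or deletion."""

    chromosome: str
    start: int
    end: int
    n_mendelian_errors: int
    pct_het_at_informative: float
    mean_depth_proband: float
    coverage_ratio: float
    resolution: str
    parent: str  # mother | father | undetermined

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "start": self.start,
            "end": self.end,
            "n_mendelian_errors": self.n_mendelian_errors,
            "pct_het_at_informative": self.pct_het_at_informative,
            "mean_depth_proband": self.mean_depth_proband,
            "coverage_ratio": self.coverage_ratio,
            "resolution": self.resolution,
            "parent": self.parent,
        }


def resolve_region(
    trio: TrioGenotypes,
    chromosome: str,
    region: tuple,
    genome_mean_depth: float,
    ratio_min: float = 0.9,
) -> CandidateRegion:
    """Resolve one merged candidate region to partial UPD or deletion.

    The region's mean proband depth is compared to the genome-wide mean;
    only a coverage ratio strictly above ``ratio_min`` supports true UPD —
    at or below, the Mendelian-error excess is attributed to a hemizygous
    deletion.  Parent of origin comes from the match direction at the
    region's informative sites.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome_mean_depth must be positive")
    start, end = int(region[0]), int(region[1])
    sub = trio.subset(chromosome)
    sub = sub[(sub["pos"] >= start) & (sub["pos"] < end)]
    dp = sub["dp_proband"].to_numpy()
    dp = dp[dp >= 0]
    if dp.size == 0:
        raise ValueError(f"region {chromosome}:{start}-{end} has no proband depth data")
    mean_dp = float(dp.mean())
    ratio = mean_dp / genome_mean_depth

    gm = sub["gt_mother"].to_numpy()
    gf = sub["gt_father"].to_numpy()
    gp = sub["gt_proband"].to_numpy()
    informative, merror, match = _site_flags(gm, gf, gp)
    n_inf = int((informative & (gp != MISSING)).sum())
    n_het = int((match == 3).sum())
    n_mm = int((match == 1).sum())
    n_mf = int((match == 2).sum())
    if n_mm > n_mf:
        parent = MATCH_MOTHER
    elif n_mf > n_mm:
        parent = MATCH_FATHER
    else:
        parent = "undetermined"
    return CandidateRegion(
        chromosome=normalize_chrom(chromosome),
        start=start,
        end=end,
        n_mendelian_errors=int(merror.sum()),
        pct_het_at_informative=100.0 * n_het / n_inf if n_inf else nan,
        mean_depth_proband=mean_dp,
        coverage_ratio=ratio,
        resolution=RESOLUTION_PARTIAL_UPD if ratio > ratio_min else RESOLUTION_DELETION,
        parent=parent,
    )
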