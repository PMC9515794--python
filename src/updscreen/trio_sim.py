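"""Synthetic trio genotype generator.

Generates mother/father/proband genotype calls at a panel of common biallelic
SNVs with the inheritance structure the UPD screen is built to detect:
whole-chromosome isodisomy (both copies of one parental homolog) and
heterodisomy (both homologs of one parent), segmental isodisomy, hemizygous
deletions (homozygous diploid calls at half depth — the caller behaviour that
makes the coverage check necessary), trisomy-like excess heterozygosity and
parental autozygosity (consanguinity), plus genotype-error and depth/quality
noise.

Parental haplotypes are simulated explicitly (two alleles per parent per
site, independent across sites, Hardy–Weinberg at the panel frequency):
isodisomy duplicates one chosen homolog, heterodisomy transmits both.  The
screen uses no linkage information, so site independence is adequate.

Default chromosome lengths are GRCh38 lengths scaled down by 10 so that a
desk-scale panel (~2,000 sites/chromosome) reproduces the per-5 Mb-window
site density regime of a whole-genome screen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotype_store import HET, HOM_ALT, HOM_REF, MISSING, ROLES, normalize_chrom

__all__ = [
    "GRCH38_LENGTHS", "default_chrom_lengths", "Event", "SimScenario",
    "TruthRecord", "simulate_site_panel", "simulate_trio", "write_trio_vcf",
    "write_pedigree", "write_truth_bed", "study_cohort",
]

#: GRCh38 primary-assembly chromosome lengths (bp).
GRCH38_LENGTHS = {
    "1": 248_956_422, "2": 242_193_529, "3": 198_295_559, "4": 190_214_555,
    "5": 181_538_259, "6": 170_805_979, "7": 159_345_973, "8": 145_138_636,
    "9": 138_394_717, "10": 133_797_422, "11": 135_086_622, "12": 133_275_309,
    "13": 114_364_328, "14": 107_043_718, "15": 101_991_189, "16": 90_338_345,
    "17": 83_257_441, "18": 80_373_285, "19": 58_617_616, "20": 64_444_167,
    "21": 46_709_983, "22": 50_818_468, "X": 156_040_895,
}

EVENT_KINDS = frozenset({
    "biparental", "upid_maternal", "upid_paternal", "uphd_maternal",
    "uphd_paternal", "partial_upid", "deletion", "trisomy_like", "autozygous",
})


def default_chrom_lengths(scale: int = 10) -> dict:
    """GRCh38 chromosome lengths divided by ``scale`` (default 10)."""
    return {c: n // scale for c, n in GRCH38_LENGTHS.items()}


@dataclass(frozen=True)
class Event:
    """One per-chromosome inheritance event.

    kind
        One of ``biparental``, ``upid_maternal``, ``upid_paternal``,
        ``uphd_maternal``, ``uphd_paternal``, ``partial_upid``, ``deletion``,
        ``trisomy_like``, ``autozygous``.
    parent
        Disomic parent for ``partial_upid`` (``mother``/``father``).
    start, end
        Half-open interval [start, end) for segmental events (1-based start).
    inherited_from
        For ``deletion``: the parent whose allele survives.
    fraction
        For ``autozygous``: fraction of the parental genome sharing a common
        haplotype.
    het_rate
        For ``trisomy_like``: per-site probability of forcing a heterozygous
        proband call on top of biparental transmission.
    """

    kind: str
    parent: str | None = None
    start: int | None = None
    end: int | None = None
    inherited_from: str | None = None
    fraction: float | None = None
    het_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "partial_upid":
            if self.parent not in ("mother", "father"):
                raise ValueError("partial_upid requires parent=mother|father")
            self._require_interval()
        if self.kind == "deletion":
            if self.inherited_from not in ("mother", "father"):
                raise ValueError("deletion requires inherited_from=mother|father")
            self._require_interval()
        if self.kind == "autozygous":
            if self.fraction is None or not 0.0 <= self.fraction <= 1.0:
                raise ValueError("autozygous requires fraction in [0, 1]")

    def _require_interval(self) -> None:
        if self.start is None or self.end is None or self.start >= self.end or self.start < 0:
            raise ValueError(f"{self.kind} requires 0 <= start < end")


@dataclass
class SimScenario:
    """Declarative per-chromosome scenario driving one simulated trio.

    Chromosomes absent from ``events`` are biparental.  At most one event per
    chromosome.  ``seed`` is mandatory: no silent entropy.
    """

    seed: int
    events: dict = field(default_factory=dict)
    genotype_error_rate: float = 3e-4
    mean_depth: float = 40.0
    depth_dispersion: float = 25.0
    gq_fail_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.genotype_error_rate <= 0.01:
            raise ValueError("genotype_error_rate must be in [0, 0.01]")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        self.events = {
            normalize_chrom(c): (e if isinstance(e, Event) else Event(**e))
            for c, e in self.events.items()
        }

    def to_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "genotype_error_rate": float(self.genotype_error_rate),
            "mean_depth": float(self.mean_depth),
            "depth_dispersion": float(self.depth_dispersion),
            "gq_fail_rate": float(self.gq_fail_rate),
            "events": {
                c: {k: v for k, v in dataclasses.asdict(e).items() if v is not None}
                for c, e in self.events.items()
            },
        }

    @classmethod
    def from_yaml(cls, path: str) -> "SimScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class TruthRecord:
    """One planted non-biparental event (interval half-open, or whole-chromosome)."""

    chrom: str
    kind: str
    parent: str  # mother | father | not_applicable
    start: int | None = None  # None => whole chromosome
    end: int | None = None


def simulate_site_panel(
    n_sites_per_chrom: int,
    chrom_lengths: dict | None = None,
    af_low: float = 0.4,
    af_high: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a panel of common biallelic SNV sites.

    Positions are drawn uniformly without replacement per chromosome and
    sorted; alternate-allele frequencies are uniform in [af_low, af_high]
    (default keeps minor allele frequency >= 0.4).  Returns a DataFrame with
    columns chrom (GRCh38-style 'chr*' labels), pos, ref, alt, af.
    """
    if n_sites_per_chrom < 1:
        raise ValueError("n_sites_per_chrom must be >= 1")
    if not 0.0 <= af_low <= af_high <= 1.0:
        raise ValueError("need 0 <= af_low <= af_high <= 1")
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    rng = np.random.default_rng(seed)
    nucs = np.array(list("ACGT"))
    frames = []
    for chrom, length in chrom_lengths.items():
        if length < n_sites_per_chrom:
            raise ValueError(
                f"chromosome {chrom} length {length} < {n_sites_per_chrom} sites"
            )
        pos = np.sort(rng.choice(length, size=n_sites_per_chrom, replace=False)) + 1
        ref_i = rng.integers(0, 4, n_sites_per_chrom)
        alt_i = (ref_i + rng.integers(1, 4, n_sites_per_chrom)) % 4
        frames.append(pd.DataFrame({
            "chrom": f"chr{normalize_chrom(chrom)}",
            "pos": pos.astype(np.int64),
            "ref": nucs[ref_i],
            "alt": nucs[alt_i],
            "af": rng.uniform(af_low, af_high, n_sites_per_chrom),
        }))
    return pd.concat(frames, ignore_index=True)


def _apply_genotype_errors(gt: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Replace calls with a uniformly chosen *different* diploid genotype."""
    if rate <= 0:
        return gt
    err = rng.random(gt.size) < rate
    shift = rng.integers(1, 3, gt.size)
    out = gt.copy()
    out[err] = (gt[err] + shift[err]) % 3
    return out


def _depths(mean: np.ndarray | float, k: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial read depths with mean ``mean`` and shape ``k``."""
    mu = np.broadcast_to(np.asarray(mean, float), (n,))
    p = k / (k + mu)
    return rng.negative_binomial(k, p).astype(np.int64)


def _gq(n: int, fail_rate: float, rng: np.random.Generator) -> np.ndarray:
    gq = np.full(n, 99, dtype=np.int64)
    bad = rng.random(n) < fail_rate
    gq[bad] = rng.integers(0, 15, int(bad.sum()))
    return gq


def simulate_trio(
    panel: pd.DataFrame,
    scenario: SimScenario,
    proband_sex: str,
    chrom_lengths: dict | None = None,
):
    """Simulate one trio over ``panel`` under ``scenario``.

    Returns ``(table, truth)`` where ``table`` is a genotype table (columns
    as in :data:`updscreen.genotype_store.REQUIRED_COLUMNS` plus the panel's
    chrom labels) and ``truth`` is a list of :class:`TruthRecord`.

    For a male proband no X-chromosome records are emitted (the screen only
    examines X in females).  For a female proband the father is hemizygous
    on X: one haplotype, reported as a homozygous diploid call at half depth.
    """
    if proband_sex not in ("male", "female"):
        raise ValueError("proband_sex must be male or female")
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    lengths = {normalize_chrom(c): n for c, n in chrom_lengths.items()}
    panel_chroms = [normalize_chrom(c) for c in pd.unique(panel["chrom"])]
    for chrom in scenario.events:
        if chrom not in panel_chroms:
            raise ValueError(f"scenario references chromosome {chrom!r} absent from panel")
        ev = scenario.events[chrom]
        if ev.start is not None and ev.end is not None:
            if ev.end > lengths.get(chrom, np.inf):
                raise ValueError(
                    f"event interval [{ev.start}, {ev.end}) exceeds chromosome {chrom} length"
                )

    rng = np.random.default_rng(scenario.seed)
    truth: list[TruthRecord] = []
    frames = []
    norm = panel["chrom"].map(normalize_chrom)
    for chrom in panel_chroms:
        if chrom == "X" and proband_sex == "male":
            continue
        sub = panel.loc[norm == chrom]
        n = len(sub)
        p = sub["af"].to_numpy(float)
        pos = sub["pos"].to_numpy(np.int64)
        ev = scenario.events.get(chrom, Event(kind="biparental"))

        # explicit parental haplotypes (alt = 1)
        mh = (rng.random((n, 2)) < p[:, None]).astype(np.int8)
        fh = (rng.random((n, 2)) < p[:, None]).astype(np.int8)
        father_hemizygous_x = chrom == "X"  # female proband reaches here
        if father_hemizygous_x:
            fh[:, 1] = fh[:, 0]

        in_ev = np.zeros(n, dtype=bool)
        if ev.start is not None and ev.end is not None:
            in_ev = (pos >= ev.start) & (pos < ev.end)

        # autozygosity: a shared ancestral haplotype carried by both parents
        # and transmitted through both, so the child is homozygous there
        az = np.zeros(n, dtype=bool)
        if ev.kind == "autozygous":
            az = rng.random(n) < ev.fraction
            shared = (rng.random(int(az.sum())) < p[az]).astype(np.int8)
            mh[az, 0] = shared
            fh[az, 0] = shared

        # biparental transmission baseline
        mt = mh[np.arange(n), rng.integers(0, 2, n)]
        ft = fh[np.arange(n), rng.integers(0, 2, n)]
        if ev.kind == "autozygous":
            mt[az] = mh[az, 0]
            ft[az] = fh[az, 0]
        gp = (mt + ft).astype(np.int8)

        kind = ev.kind
        parent = ev.parent
        if kind in ("upid_maternal", "upid_paternal", "uphd_maternal", "uphd_paternal"):
            parent = "mother" if kind.endswith("maternal") else "father"
        ph = mh if parent == "mother" else fh

        if kind in ("upid_maternal", "upid_paternal"):
            h = int(rng.integers(0, 2))
            gp = (2 * ph[:, h]).astype(np.int8)
            truth.append(TruthRecord(chrom, "upid", parent))
        elif kind in ("uphd_maternal", "uphd_paternal"):
            gp = ph.sum(axis=1).astype(np.int8)
            truth.append(TruthRecord(chrom, "uphd", parent))
        elif kind == "partial_upid":
            h = int(rng.integers(0, 2))
            gp[in_ev] = 2 * ph[in_ev, h]
            truth.append(TruthRecord(chrom, "partial_upid", parent, ev.start, ev.end))
        elif kind == "deletion":
            surviving = mt if ev.inherited_from == "mother" else ft
            gp[in_ev] = 2 * surviving[in_ev]
            truth.append(TruthRecord(chrom, "deletion", ev.inherited_from, ev.start, ev.end))
        elif kind == "trisomy_like":
            forced = rng.random(n) < ev.het_rate
            gp[forced] = HET
            truth.append(TruthRecord(chrom, "trisomy_like", "not_applicable"))
        elif kind == "autozygous":
            truth.append(TruthRecord(chrom, "autozygous", "not_applicable"))

        gm = mh.sum(axis=1).astype(np.int8)
        gf = fh.sum(axis=1).astype(np.int8)
        e = scenario.genotype_error_rate
        gm = _apply_genotype_errors(gm, e, rng)
        gf = _apply_genotype_errors(gf, e, rng)
        gp = _apply_genotype_errors(gp, e, rng)

        k = scenario.depth_dispersion
        mu = scenario.mean_depth
        dp_m = _depths(mu, k, n, rng)
        mu_f = np.full(n, mu / 2.0 if father_hemizygous_x else mu)
        dp_f = _depths(mu_f, k, n, rng)
        mu_p = np.full(n, float(mu))
        if kind == "deletion":
            mu_p[in_ev] = mu / 2.0
        dp_p = _depths(mu_p, k, n, rng)

        frames.append(pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "pos": pos,
            "ref": sub["ref"].to_numpy(),
            "alt": sub["alt"].to_numpy(),
            "af": p,
            "gt_mother": gm.astype(np.int64),
            "gt_father": gf.astype(np.int64),
            "gt_proband": gp.astype(np.int64),
            "dp_mother": dp_m,
            "dp_father": dp_f,
            "dp_proband": dp_p,
            "gq_mother": _gq(n, scenario.gq_fail_rate, rng),
            "gq_father": _gq(n, scenario.gq_fail_rate, rng),
            "gq_proband": _gq(n, scenario.gq_fail_rate, rng),
        }))

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(columns=[
            "chrom", "pos", "ref", "alt", "af",
            "gt_mother", "gt_father", "gt_proband",
            "dp_mother", "dp_father", "dp_proband",
            "gq_mother", "gq_father", "gq_proband",
        ])
    return table, truth


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_trio_vcf(
    table: pd.DataFrame,
    path: str,
    samples: tuple = ("MOTHER", "FATHER", "PROBAND"),
    chrom_lengths: dict | None = None,
    af_field: str = "AF",
) -> None:
    """Write a trio genotype table as VCF v4.2 (GT:DP:GQ, INFO AF).

    Sample column order is (mother, father, proband).  ``path`` ending in
    ``.gz`` is bgzip-compressed and tabix-indexed via pysam.
    """
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    if not table.empty and not table.groupby("chrom", sort=False)["pos"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    ).all():
        raise ValueError("table must be position-sorted within chromosomes")

    gz = str(path).endswith(".gz")
    plain = str(path) + ".tmp" if gz else str(path)
    with open(plain, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=updscreen-trio-sim\n")
        for chrom, length in chrom_lengths.items():
            out.write(f"##contig=<ID=chr{normalize_chrom(chrom)},length={int(length)}>\n")
        out.write(
            f'##INFO=<ID={af_field},Number=A,Type=Float,'
            'Description="Alternate allele population frequency">\n'
        )
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        out.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        cols = [table[c].to_numpy() for c in (
            "chrom", "pos", "ref", "alt", "af",
            "gt_mother", "dp_mother", "gq_mother",
            "gt_father", "dp_father", "gq_father",
            "gt_proband", "dp_proband", "gq_proband",
        )] if not table.empty else []
        if cols:
            for chrom, pos, ref, alt, af, gm, dm, qm, gf, df_, qf, gp, dp, qp in zip(*cols):
                c = f"chr{normalize_chrom(chrom)}"
                out.write(
                    f"{c}\t{int(pos)}\t.\t{ref}\t{alt}\t.\tPASS\t{af_field}={float(af):.4f}\t"
                    f"GT:DP:GQ\t{_GT_STR[int(gm)]}:{int(dm)}:{int(qm)}\t"
                    f"{_GT_STR[int(gf)]}:{int(df_)}:{int(qf)}\t"
                    f"{_GT_STR[int(gp)]}:{int(dp)}:{int(qp)}\n"
                )
    if gz:
        import pysam

        pysam.tabix_compress(plain, str(path), force=True)
        pysam.tabix_index(str(path), preset="vcf", force=True)
        import os

        os.remove(plain)


def write_pedigree(
    path: str,
    samples: tuple = ("MOTHER", "FATHER", "PROBAND"),
    proband_sex: str = "female",
    family: str = "FAM1",
) -> None:
    mother, father, proband = samples
    sex = "1" if proband_sex == "male" else "2"
    with open(path, "w") as out:
        out.write(f"{family}\t{father}\t0\t0\t1\t1\n")
        out.write(f"{family}\t{mother}\t0\t0\t2\t1\n")
        out.write(f"{family}\t{proband}\t{father}\t{mother}\t{sex}\t2\n")


def write_truth_bed(
    truth: list,
    path: str,
    proband: str = "PROBAND",
    chrom_lengths: dict | None = None,
) -> None:
    """Write planted events as BED (0-based half-open): chrom, start, end, proband, event, parent."""
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    lengths = {normalize_chrom(c): n for c, n in chrom_lengths.items()}
    with open(path, "w") as out:
        for rec in truth:
            chrom = normalize_chrom(rec.chrom)
            if rec.start is None:
                start, end = 0, lengths[chrom]
            else:
                start, end = rec.start - 1, rec.end - 1
            out.write(f"chr{chrom}\t{start}\t{end}\t{proband}\t{rec.kind}\t{rec.parent}\n")


# ---------------------------------------------------------------------------
# study-scale cohort

@dataclass(frozen=True)
class CohortMember:
    proband_id: str
    sex: str
    scenario: SimScenario


def study_cohort(
    seed: int,
    n_trios: int = 164,
    n_sites_per_chrom: int = 2000,
    genotype_error_rate: float = 3e-4,
    mean_depth: float = 40.0,
    depth_dispersion: float = 25.0,
    chrom_lengths: dict | None = None,
):
    """Build the screen's reference synthetic cohort.

    164 trios (95 male / 69 female probands), one shared common-SNV panel,
    and the planted inheritance events the screen is designed to separate:

    * P001 — maternal whole-chromosome isodisomy of chr1
    * P002, P003 — paternal whole-chromosome isodisomy of chr2
    * P004 — maternal heterodisomy of chr15
    * P005 — 8 Mb hemizygous deletion on chr4 (maternal allele retained)
    * P006 — 6 Mb hemizygous deletion on chr9 (paternal allele retained)
    * P007 — trisomy-like excess heterozygosity on chr21
    * P008–P010 — parental autozygosity, fraction 0.25, genome-wide

    Intervals scale with ``chrom_lengths`` (fractions of the chromosome).
    Returns ``(panel, members, chrom_lengths)``; simulate each member with
    :func:`simulate_trio`.
    """
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    rng = np.random.default_rng(seed)
    panel = simulate_site_panel(
        n_sites_per_chrom, chrom_lengths, seed=int(rng.integers(0, 2**31 - 1))
    )
    n_female = round(n_trios * 69 / 164)
    sexes = np.array(["female"] * n_female + ["male"] * (n_trios - n_female))
    rng.shuffle(sexes)

    len4 = chrom_lengths["4"]
    len9 = chrom_lengths["9"]
    del4 = Event("deletion", start=int(0.3 * len4), end=int(0.3 * len4) + 8_000_000,
                 inherited_from="mother")
    del9 = Event("deletion", start=int(0.2 * len9), end=int(0.2 * len9) + 6_000_000,
                 inherited_from="father")
    planted = {
        0: {"1": Event("upid_maternal")},
        1: {"2": Event("upid_paternal")},
        2: {"2": Event("upid_paternal")},
        3: {"15": Event("uphd_maternal")},
        4: {"4": del4},
        5: {"9": del9},
        6: {"21": Event("trisomy_like")},
    }
    for i in (7, 8, 9):
        planted[i] = {c: Event("autozygous", fraction=0.25) for c in chrom_lengths}

    members = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n_trios)
    for i in range(n_trios):
        members.append(CohortMember(
            proband_id=f"P{i + 1:03d}",
            sex=str(sexes[i]),
            scenario=SimScenario(
                seed=int(child_seeds[i]),
                events=planted.get(i, {}),
                genotype_error_rate=genotype_error_rate,
                mean_depth=mean_depth,
                depth_dispersion=depth_dispersion,
            ),
        ))
    return panel, members, chrom_lengths
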