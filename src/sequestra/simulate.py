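"""Synthetic cattery generator: pedigrees, phenotypes, genotypes.

Two kinds of inputs are produced:

* **Stochastic cohorts** shaped like the source cattery — a handful of sires,
  a few dozen dams each mostly mated to one sire, and several hundred kittens
  over a twenty-year span — with binary phenotypes drawn from the same
  generative model the animal model assumes (logistic liability with
  recursive breeding values), plus Mendelian-consistent SNP panels by gene
  dropping.  These carry their simulation truth along so recovery can be
  measured.

* A **deterministic margin ledger**: a pedigree whose per-dam and per-sire
  case/control margins equal the published tables cell for cell, so the exact
  odds-ratio stage can be exercised against printed values without any data
  download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .gwas import GenotypeMatrix
from .pedigree import Pedigree, PedigreeRecord, mendelian_sampling_sd

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_pedigree",
    "simulate_phenotypes",
    "simulate_genotypes",
    "simulate_cohort",
    "make_paper_margin_ledger",
    "gwas_case_control_subset",
    "inject_mendelian_errors",
]

_STAGE = {"pedigree": 1, "phenotype": 2, "genotype": 3, "subset": 4}


def _stage_rng(seed: int | None, stage: str) -> np.random.Generator:
    """Independent per-stage substream of the master seed."""
    ss = np.random.SeedSequence([0 if seed is None else seed, _STAGE[stage]])
    return np.random.Generator(np.random.PCG64(ss))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cattery.

    The defaults emulate the study cattery: 3 sires and 43 dams producing
    roughly 757 kittens between 2002 and 2021, ~8% baseline prevalence on the
    liability scale, a very high additive SD (sigma_a = 4.9, i.e. h2 ~ 0.96),
    dams nested within sires, and a small SNP panel for the case/control
    stage.
    """

    # pedigree shape
    n_sires: int = 3
    n_dams: int = 43
    year_start: int = 2002
    year_end: int = 2021
    dam_career_years: int = 6
    litters_per_dam_mean: float = 4.5
    litter_size_mean: float = 3.9
    sire_weights: tuple[float, ...] = (0.59, 0.27, 0.14)
    sire_fidelity: float = 0.9
    # generative phenotype model (logit scale)
    sigma_a: float = 4.9
    base_prevalence: float = 0.081
    beta_year: float = -0.02
    beta_sex: float = 0.3
    underreporting: float = 0.0
    # genotype panel
    n_variants: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    genotype_missing_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.n_dams < 1 or self.n_sires < 1:
            raise ValueError("need at least one dam and one sire")
        if len(self.sire_weights) != self.n_sires:
            raise ValueError("sire_weights length must equal n_sires")
        if not 0.0 < self.base_prevalence < 1.0:
            raise ValueError("base_prevalence must be in (0, 1)")
        if self.sigma_a < 0:
            raise ValueError("sigma_a must be non-negative")
        if not 0.0 <= self.underreporting <= 1.0:
            raise ValueError("underreporting must be a probability")
        if self.litter_size_mean < 1:
            raise ValueError("mean litter size must be at least 1")


@dataclass
class SyntheticCohort:
    """A simulated cattery with its generative truth attached."""

    pedigree: Pedigree                  # statuses = recorded (post-reporting)
    true_breeding_values: pd.Series
    liability: pd.Series                # linear predictor eta per animal
    true_status: pd.Series              # bool: actually affected
    recorded_status: pd.Series          # affected / unaffected / unknown
    config: SimulationConfig
    seed: int | None
    genotypes: GenotypeMatrix | None = None


def simulate_pedigree(cfg: SimulationConfig, seed: int | None = None) -> Pedigree:
    """Sires, dams, and litters of kittens; deterministic given the seed.

    Each dam gets a primary sire (weights ~ the sires' offspring shares) and
    a breeding-career window inside the year span; each litter goes to the
    primary sire with probability ``sire_fidelity``.  Kitten counts are
    Poisson around the configured litter rates, so the default preset lands
    within a few percent of 757 kittens.
    """
    rng = _stage_rng(seed, "pedigree")
    records: list[PedigreeRecord] = []
    sires = [f"sire{i + 1}" for i in range(cfg.n_sires)]
    dams = [f"dam{i + 1}" for i in range(cfg.n_dams)]
    for i, sid in enumerate(sires):
        records.append(
            PedigreeRecord(id=sid, sex="male",
                           birth_year=cfg.year_start - 2 - i)
        )
    for did in dams:
        records.append(
            PedigreeRecord(id=did, sex="female",
                           birth_year=cfg.year_start - int(rng.integers(1, 7)))
        )
    weights = np.asarray(cfg.sire_weights, dtype=float)
    weights = weights / weights.sum()
    kitten = 0
    for did in dams:
        primary = sires[int(rng.choice(cfg.n_sires, p=weights))]
        span = cfg.year_end - cfg.year_start + 1
        career = min(cfg.dam_career_years, span)
        start = cfg.year_start + int(rng.integers(0, span - career + 1))
        n_litters = max(1, int(rng.poisson(cfg.litters_per_dam_mean)))
        for _ in range(n_litters):
            year = start + int(rng.integers(0, career))
            if rng.random() < cfg.sire_fidelity or cfg.n_sires == 1:
                litter_sire = primary
            else:
                others = [s for s in sires if s != primary]
                litter_sire = others[int(rng.integers(0, len(others)))]
            size = 1 + int(rng.poisson(cfg.litter_size_mean - 1.0))
            for _ in range(size):
                kitten += 1
                records.append(
                    PedigreeRecord(
                        id=f"k{kitten:04d}",
                        sire=litter_sire,
                        dam=did,
                        sex="male" if rng.random() < 0.5 else "female",
                        birth_year=year,
                    )
                )
    return Pedigree(records)


def simulate_phenotypes(
    ped: Pedigree, cfg: SimulationConfig, seed: int | None = None
) -> SyntheticCohort:
    """Draw breeding values and binary statuses under the liability model.

    ``a_i = sigma_a s_i z_i + (a_sire + a_dam)/2`` with z ~ N(0,1), then
    ``P(affected) = logistic(beta0 + beta_year * year_c + beta_sex * male +
    a_i)`` with ``beta0 = logit(base_prevalence)``.  Every animal (founders
    included) gets a true status, so affected dams arise naturally; recorded
    status flips affected -> unknown with the underreporting probability.
    """
    rng = _stage_rng(seed, "phenotype")
    n = len(ped)
    s = mendelian_sampling_sd(ped).to_numpy()
    z = rng.standard_normal(n)
    si, di = ped.sire_indices, ped.dam_indices
    a = np.empty(n)
    for i in range(n):
        parent = 0.0
        if si[i] >= 0:
            parent += a[si[i]]
        if di[i] >= 0:
            parent += a[di[i]]
        a[i] = cfg.sigma_a * s[i] * z[i] + 0.5 * parent

    years = np.array(
        [np.nan if r.birth_year is None else float(r.birth_year) for r in ped]
    )
    year_c = np.where(np.isnan(years), 0.0, years - np.nanmean(years))
    male = np.array([1.0 if r.sex == "male" else 0.0 for r in ped])
    eta = logit(cfg.base_prevalence) + cfg.beta_year * year_c + cfg.beta_sex * male + a
    affected = rng.random(n) < expit(eta)
    hidden = affected & (rng.random(n) < cfg.underreporting)
    recorded = np.where(
        affected, np.where(hidden, "unknown", "affected"), "unaffected"
    )
    ids = ped.ids
    ped_out = ped.with_statuses(dict(zip(ids, recorded)))
    return SyntheticCohort(
        pedigree=ped_out,
        true_breeding_values=pd.Series(a, index=ids, name="a"),
        liability=pd.Series(eta, index=ids, name="eta"),
        true_status=pd.Series(affected, index=ids, name="affected"),
        recorded_status=pd.Series(recorded, index=ids, name="recorded"),
        config=cfg,
        seed=seed,
    )


_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("A", "T"), ("C", "G"),
                 ("C", "T"), ("G", "T"))


def simulate_genotypes(
    ped: Pedigree,
    cfg: SimulationConfig,
    seed: int | None = None,
    sample_ids: list[str] | None = None,
    chromosomes: tuple[str, ...] = ("A1", "A2", "B1", "C1", "D1"),
) -> GenotypeMatrix:
    """Gene-drop a biallelic SNP panel through the whole pedigree.

    Founder gametes are Bernoulli draws from per-variant allele frequencies
    uniform on [maf_low, maf_high]; every other animal inherits one randomly
    chosen allele from each parent, so the panel is Mendelian-consistent by
    construction.  Missing calls are masked at random afterwards.  The
    returned matrix is restricted to ``sample_ids`` (default: all animals),
    with case/control labels from the pedigree statuses.
    """
    rng = _stage_rng(seed, "genotype")
    n, m = len(ped), cfg.n_variants
    freq = rng.uniform(cfg.maf_low, cfg.maf_high, size=m)
    gametes = np.zeros((n, m, 2), dtype=np.int8)
    si, di = ped.sire_indices, ped.dam_indices
    for i in range(n):
        for slot, p in ((0, si[i]), (1, di[i])):
            if p < 0:
                gametes[i, :, slot] = rng.random(m) < freq
            else:
                pick = rng.integers(0, 2, size=m)
                gametes[i, :, slot] = gametes[p, np.arange(m), pick]
    calls = gametes.sum(axis=2).astype(float)
    if cfg.genotype_missing_rate > 0:
        calls[rng.random((n, m)) < cfg.genotype_missing_rate] = np.nan

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    chrom = np.sort(rng.integers(0, len(chromosomes), size=m))
    pos = np.empty(m, dtype=int)
    for c in range(len(chromosomes)):
        k = int((chrom == c).sum())
        pos[chrom == c] = np.sort(
            rng.choice(np.arange(1, 10_000_000), size=k, replace=False)
        )
    variants = pd.DataFrame(
        {
            "chrom": [chromosomes[c] for c in chrom],
            "pos": pos,
            "vid": [f"Chr{chromosomes[c]}.{p}" for c, p in zip(chrom, pos)],
            "allele1": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "allele2": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )
    label_map = {"affected": "case", "unaffected": "control", "unknown": None}
    samples = pd.DataFrame(
        {
            "id": ped.ids,
            "fid": "CATTERY",
            "sire": [r.sire for r in ped],
            "dam": [r.dam for r in ped],
            "sex": [r.sex for r in ped],
            "label": [label_map[r.status] for r in ped],
        }
    )
    gm = GenotypeMatrix(samples, variants, calls)
    if sample_ids is not None:
        keep = samples["id"].isin(set(sample_ids)).to_numpy()
        gm = gm.take_samples(keep)
    return gm


def simulate_cohort(
    cfg: SimulationConfig | None = None,
    seed: int | None = None,
    genotypes: bool = False,
) -> SyntheticCohort:
    """Pedigree + phenotypes (+ optional genotype panel) in one call."""
    cfg = cfg or SimulationConfig()
    ped = simulate_pedigree(cfg, seed)
    cohort = simulate_phenotypes(ped, cfg, seed)
    if genotypes:
        cohort.genotypes = simulate_genotypes(cohort.pedigree, cfg, seed)
    return cohort


def gwas_case_control_subset(
    cohort: SyntheticCohort,
    n_cases: int = 14,
    n_controls: int = 10,
    seed: int | None = None,
) -> list[str]:
    """Pick a well-phenotyped case/control subset with parent links.

    Mirrors the study design: cases are affected animals (affected dams
    first, then affected kittens), controls are healthy breeding animals and
    kittens, so parent-offspring duos are present in the genotyped set.
    """
    rng = _stage_rng(seed, "subset")
    ped = cohort.pedigree
    affected = [r.id for r in ped if r.status == "affected"]
    healthy = [r.id for r in ped if r.status == "unaffected"]
    aff_parents = [i for i in affected if ped.record(i).is_founder]
    aff_kittens = [i for i in affected if not ped.record(i).is_founder]
    if len(affected) < n_cases or len(healthy) < n_controls:
        raise ValueError("cohort too small for the requested subset")
    cases = (aff_parents + list(rng.permutation(aff_kittens)))[:n_cases]
    healthy_parents = [i for i in healthy if ped.record(i).is_founder]
    healthy_kittens = [i for i in healthy if not ped.record(i).is_founder]
    controls = (healthy_parents[:1] + list(rng.permutation(healthy_kittens)))
    controls = controls[:n_controls]
    return list(cases) + list(controls)


def inject_mendelian_errors(
    gm: GenotypeMatrix, variant_index: int, n_errors: int,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Force ``n_errors`` duo incompatibilities at one variant.

    Offspring with a genotyped parent get their call set to the opposite
    homozygote of that parent (parent first made homozygous if needed), which
    a duo check flags as an error.  Used to exercise the Mendelian-error QC
    filter.
    """
    rng = _stage_rng(seed, "genotype")
    idx = {sid: i for i, sid in enumerate(gm.samples["id"])}
    candidates = []
    for i, row in gm.samples.iterrows():
        for parent in (row.get("sire"), row.get("dam")):
            if isinstance(parent, str) and parent in idx:
                candidates.append((i, idx[parent]))
                break
    if len(candidates) < n_errors:
        raise ValueError("not enough genotyped duos to plant errors")
    calls = gm.calls.copy()
    chosen = rng.permutation(len(candidates))[:n_errors]
    for c in chosen:
        child, parent = candidates[c]
        p = calls[parent, variant_index]
        if np.isnan(p) or p == 1:
            p = 0.0
            calls[parent, variant_index] = p
        calls[child, variant_index] = 2.0 - p
    return GenotypeMatrix(gm.samples.copy(), gm.variants.copy(), calls)


# ---------------------------------------------------------------------------
# the deterministic margin ledger
# ---------------------------------------------------------------------------

#: per-dam (cases, controls) margins of the published dam table, in table order
_DAM_MARGINS = [
    (17, 17), (9, 33), (4, 12), (1, 34), (1, 2), (2, 11), (2, 11),
    (1, 4), (4, 27), (4, 28), (2, 37), (2, 15), (2, 17), (1, 17),
    (1, 14), (1, 18), (1, 15), (1, 13), (1, 12), (3, 36), (1, 9),
]

#: dam table row (1-based) -> sire; chosen so the per-sire margins
#: (45, 342), (9, 166), (7, 86) hold simultaneously with the dam margins,
#: with dams 1 and 2 always mated to sire 1.
_DAM_TO_SIRE = {
    1: 1, 2: 1, 3: 1, 5: 1, 7: 1, 8: 1, 12: 1, 13: 1, 14: 1,
    15: 1, 16: 1, 17: 1, 18: 1, 19: 1, 21: 1,
    10: 2, 11: 2, 20: 2,
    4: 3, 6: 3, 9: 3,
}

#: control counts of the 22 dams with no affected offspring (unlisted in the
#: dam table); they contribute the remaining 594 - 382 = 212 pre-cutoff
#: controls, split by sire as 133 / 65 / 14.
_UNLISTED = [(1, c) for c in [10] * 10 + [11] * 3] + \
            [(2, c) for c in [11] * 5 + [10]] + \
            [(3, c) for c in [5, 5, 4]]

#: post-cutoff control kittens (born 2020-2021): 102 spread over healthy
#: unlisted dams, bringing the all-years totals to 757 progeny / 61 affected.
_POST_CUTOFF_PER_DAM = 6
_POST_CUTOFF_DAMS = 17

_AFFECTED_YEARS = tuple(range(2006, 2020))
_CONTROL_YEARS = tuple(range(2002, 2020))
_N_AFFECTED_MALES = 35  # of the 61 affected cats, 35 were male


def make_paper_margin_ledger() -> Pedigree:
    """Deterministic pedigree reproducing the published table margins.

    Per-dam case/control counts match the dam table cell for cell, per-sire
    counts sum to (45, 342), (9, 166), (7, 86) — 61 cases / 594 controls
    among the 655 offspring born up to 2019 — and dams 2 and 3 are recorded
    affected, so the parental-phenotype summary yields 13/58 (22%) for one
    affected parent, 48/699 (6.9%) for two healthy parents, and 61/757
    (8.1%) overall.  (The published dam-table case column sums to exactly 61
    and its control column to 382; the 22 dams without affected offspring
    account for the remaining 212 pre-cutoff controls.)

    Birth years are filled deterministically: affected kittens cycle over
    2006-2019, pre-cutoff controls over 2002-2019, and the 102 post-2019
    control kittens alternate 2020/2021.
    """
    records: list[PedigreeRecord] = []
    for i in range(3):
        records.append(
            PedigreeRecord(id=f"sire{i + 1}", sex="male", birth_year=2000,
                           status="unaffected")
        )
    n_dams = len(_DAM_MARGINS) + len(_UNLISTED)
    for i in range(n_dams):
        status = "affected" if (i + 1) in (2, 3) else "unaffected"
        records.append(
            PedigreeRecord(id=f"dam{i + 1}", sex="female", birth_year=2000,
                           status=status)
        )

    kitten = 0
    affected_count = 0
    control_count = 0

    def add_kitten(dam_no: int, sire_no: int, affected: bool, year: int):
        nonlocal kitten, affected_count, control_count
        kitten += 1
        if affected:
            sex = "male" if affected_count < _N_AFFECTED_MALES else "female"
            affected_count += 1
        else:
            sex = "male" if control_count % 2 == 0 else "female"
            control_count += 1
        records.append(
            PedigreeRecord(
                id=f"k{kitten:04d}",
                sire=f"sire{sire_no}",
                dam=f"dam{dam_no}",
                sex=sex,
                birth_year=year,
                status="affected" if affected else "unaffected",
            )
        )

    aff_i = 0
    ctl_i = 0
    for row, (cases, controls) in enumerate(_DAM_MARGINS, start=1):
        sire_no = _DAM_TO_SIRE[row]
        for _ in range(cases):
            add_kitten(row, sire_no, True, _AFFECTED_YEARS[aff_i % len(_AFFECTED_YEARS)])
            aff_i += 1
        for _ in range(controls):
            add_kitten(row, sire_no, False, _CONTROL_YEARS[ctl_i % len(_CONTROL_YEARS)])
            ctl_i += 1
    for off, (sire_no, controls) in enumerate(_UNLISTED):
        dam_no = len(_DAM_MARGINS) + 1 + off
        for _ in range(controls):
            add_kitten(dam_no, sire_no, False,
                       _CONTROL_YEARS[ctl_i % len(_CONTROL_YEARS)])
            ctl_i += 1
    # post-cutoff kittens: healthy, born 2020-2021, from unlisted dams
    post = 0
    for off in range(_POST_CUTOFF_DAMS):
        dam_no = len(_DAM_MARGINS) + 1 + off
        sire_no = _UNLISTED[off][0]
        for _ in range(_POST_CUTOFF_PER_DAM):
            add_kitten(dam_no, sire_no, False, 2020 + post % 2)
            post += 1
    return Pedigree(records)
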