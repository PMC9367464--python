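"""Case/control association stage: PLINK text I/O, QC, exact tests, Holm.

The quality-control pipeline follows the fixed order sample call rate ->
variant call rate -> Mendelian errors -> minor allele frequency, with every
threshold a strict inequality (a sample or variant sitting exactly on the
boundary is retained): samples with call rate *below* 0.95 are dropped, then
variants with call rate below 0.95, *more than one* Mendelian error across
the genotyped duos/trios, or MAF *below* 0.05.  Each surviving biallelic
variant is tested with a two-sided Fisher exact test on the 2x2 allele-count
table (cases vs controls); p-values are Holm-adjusted, and the genome-wide
Bonferroni line is alpha / m.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exact import ContingencyTable2x2, fisher_exact_p

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "AssociationResult",
    "read_plink_text",
    "write_plink_text",
    "sample_call_rate_filter",
    "mendelian_error_count",
    "variant_filters",
    "allelic_fisher",
    "holm_adjust",
    "genomewide_threshold",
    "manhattan_qq_tables",
    "run_association",
    "subset_rerun",
    "CAT_CHROMOSOME_ORDER",
]

#: natural order of the feline karyotype for plotting / sorting
CAT_CHROMOSOME_ORDER = (
    "A1", "A2", "A3", "B1", "B2", "B3", "B4", "C1", "C2",
    "D1", "D2", "D3", "D4", "E1", "E2", "E3", "F1", "F2", "X",
)


class GwasDataError(ValueError):
    """Malformed genotype input or an empty analysis set."""


@dataclass
class GenotypeMatrix:
    """Samples x variants additive genotype calls.

    ``samples`` needs columns id, label (``case`` / ``control`` / missing) and
    optionally sire, dam, age.  ``variants`` needs chrom, pos, vid, allele1,
    allele2.  ``calls[i, j]`` counts copies of allele2 (0/1/2), NaN = missing.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise GwasDataError("calls shape does not match samples x variants")
        if self.variants["vid"].duplicated().any():
            dup = self.variants["vid"][self.variants["vid"].duplicated()].iloc[0]
            raise GwasDataError(f"duplicate variant id {dup!r}")
        if self.variants["chrom"].isna().any() or self.variants["pos"].isna().any():
            raise GwasDataError("variant chromosome/position must be non-missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_samples(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples.loc[mask].reset_index(drop=True),
            self.variants.copy(),
            self.calls[mask],
        )

    def take_variants(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples.copy(),
            self.variants.loc[mask].reset_index(drop=True),
            self.calls[:, mask],
        )

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.calls), axis=1)

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.calls), axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.calls, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        return np.minimum(freq, 1.0 - freq)


@dataclass
class QcReport:
    """Bookkeeping of the QC cascade, in the order the filters were applied."""

    steps: list[dict] = field(default_factory=list)
    n_samples_in: int = 0
    n_variants_in: int = 0
    n_samples_out: int = 0
    n_variants_out: int = 0

    def add(self, filter_name: str, axis: str, removed: int, remaining: int,
            **extra) -> None:
        self.steps.append(
            dict(filter=filter_name, axis=axis, removed=removed,
                 remaining=remaining, **extra)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


# ---------------------------------------------------------------------------
# PLINK text I/O
# ---------------------------------------------------------------------------

_PHENO_MAP = {"2": "case", "1": "control", "0": None, "-9": None}


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    PED columns: FID IID father mother sex phenotype, then two allele tokens
    per variant ("0" = missing call).  Phenotype 2 = case, 1 = control,
    0 / -9 = missing label.  The additive code counts the second distinct
    allele observed at each variant; more than two observed alleles is an
    error.
    """
    variants = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos"], dtype=str,
    )
    variants = pd.DataFrame(
        {
            "chrom": variants["chrom"],
            "pos": variants["pos"].astype(int),
            "vid": variants["vid"],
        }
    )
    m = len(variants)

    sample_rows, geno_rows = [], []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 6 + 2 * m:
                raise GwasDataError(
                    f"PED line {line_no}: expected {6 + 2 * m} fields "
                    f"({m} variants), got {len(toks)}"
                )
            fid, iid, father, mother, sex, pheno = toks[:6]
            sample_rows.append(
                dict(
                    id=iid,
                    fid=fid,
                    sire=None if father == "0" else father,
                    dam=None if mother == "0" else mother,
                    sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                    label=_PHENO_MAP.get(pheno, None),
                )
            )
            geno_rows.append(toks[6:])

    n = len(sample_rows)
    calls = np.full((n, m), np.nan)
    a1 = np.array([None] * m, dtype=object)
    a2 = np.array([None] * m, dtype=object)
    for i, row in enumerate(geno_rows):
        for j in range(m):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                if x != y:
                    raise GwasDataError(
                        f"half-missing call {x}/{y} at variant {j} sample {i}"
                    )
                continue
            code = 0
            for allele in (x, y):
                if a1[j] is None:
                    a1[j] = allele
                if allele == a1[j]:
                    continue
                if a2[j] is None:
                    a2[j] = allele
                if allele == a2[j]:
                    code += 1
                else:
                    raise GwasDataError(
                        f"variant {variants['vid'][j]!r} has >2 alleles: "
                        f"{a1[j]}, {a2[j]}, {allele}"
                    )
            calls[i, j] = code
    variants["allele1"] = a1
    variants["allele2"] = a2
    return GenotypeMatrix(pd.DataFrame(sample_rows), variants, calls)


def write_plink_text(gm: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PLINK text PED/MAP (lossless round trip with read_plink_text)."""
    with open(map_path, "w") as fh:
        for v in gm.variants.itertuples(index=False):
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\n")
    sex_code = {"male": "1", "female": "2"}
    label_code = {"case": "2", "control": "1"}
    a1 = gm.variants["allele1"].to_numpy()
    a2 = gm.variants["allele2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, s in enumerate(gm.samples.itertuples(index=False)):
            fid = getattr(s, "fid", None) or "FAM"
            toks = [
                str(fid),
                s.id,
                s.sire if isinstance(s.sire, str) else "0",
                s.dam if isinstance(s.dam, str) else "0",
                sex_code.get(getattr(s, "sex", "unknown"), "0"),
                label_code.get(s.label, "0"),
            ]
            for j in range(gm.n_variants):
                g = gm.calls[i, j]
                if np.isnan(g):
                    toks += ["0", "0"]
                elif g == 0:
                    toks += [a1[j], a1[j]]
                elif g == 1:
                    toks += [a1[j], a2[j]]
                else:
                    toks += [a2[j], a2[j]]
            fh.write(" ".join(toks) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def sample_call_rate_filter(
    gm: GenotypeMatrix, threshold: float = 0.95
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop samples whose call rate is strictly below the threshold."""
    rates = gm.call_rate_samples()
    keep = rates >= threshold
    if not keep.any():
        raise GwasDataError("sample call-rate filter removed every sample")
    report = QcReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants)
    report.add("sample_call_rate", "samples",
               int((~keep).sum()), int(keep.sum()), threshold=threshold)
    out = gm.take_samples(keep)
    report.n_samples_out = out.n_samples
    report.n_variants_out = out.n_variants
    return out, report


_TRIO_OK = {
    (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
    (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
}


def mendelian_error_count(gm: GenotypeMatrix) -> np.ndarray:
    """Per-variant count of parent-offspring incompatibilities.

    Uses trios when both parents are genotyped, otherwise duos.  A duo is
    incompatible only for opposite homozygotes (codes 0 vs 2).  Pairs/trios
    with any missing call at the variant contribute nothing.
    """
    idx = {sid: i for i, sid in enumerate(gm.samples["id"])}
    errors = np.zeros(gm.n_variants, dtype=int)
    sires = gm.samples.get("sire")
    dams = gm.samples.get("dam")
    if sires is None and dams is None:
        return errors
    for i, sid in enumerate(gm.samples["id"]):
        si = idx.get(sires.iloc[i]) if sires is not None and isinstance(sires.iloc[i], str) else None
        di = idx.get(dams.iloc[i]) if dams is not None and isinstance(dams.iloc[i], str) else None
        child = gm.calls[i]
        if si is not None and di is not None:
            p1, p2 = gm.calls[si], gm.calls[di]
            ok = ~np.isnan(child) & ~np.isnan(p1) & ~np.isnan(p2)
            for j in np.nonzero(ok)[0]:
                key = tuple(sorted((int(p1[j]), int(p2[j]))))
                if int(child[j]) not in _TRIO_OK[key]:
                    errors[j] += 1
        else:
            pi = si if si is not None else di
            if pi is None:
                continue
            p = gm.calls[pi]
            ok = ~np.isnan(child) & ~np.isnan(p)
            errors[ok.nonzero()[0]] += (
                np.abs(child[ok] - p[ok]) == 2
            ).astype(int)
    return errors


def variant_filters(
    gm: GenotypeMatrix,
    call_rate: float = 0.95,
    mendel_max: int = 1,
    maf_min: float = 0.05,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant-level QC: call rate, Mendelian errors, MAF (strict boundaries).

    A variant is dropped when its call rate is below ``call_rate``, its
    Mendelian error count exceeds ``mendel_max``, or its MAF is below
    ``maf_min`` (computed from non-missing calls of the retained samples).
    Per-criterion removal counts are recorded; a variant may fail several.
    """
    if report is None:
        report = QcReport(n_samples_in=gm.n_samples, n_variants_in=gm.n_variants)
    rates = gm.call_rate_variants()
    mendel = mendelian_error_count(gm)
    maf = gm.maf()
    fail_rate = rates < call_rate
    fail_mendel = mendel > mendel_max
    fail_maf = maf < maf_min
    keep = ~(fail_rate | fail_mendel | fail_maf)
    if not keep.any():
        raise GwasDataError("variant filters removed every variant")
    report.add("variant_call_rate", "variants", int(fail_rate.sum()),
               int((~fail_rate).sum()), threshold=call_rate)
    report.add("mendelian_errors", "variants", int(fail_mendel.sum()),
               int((~fail_mendel).sum()), max_errors=mendel_max)
    report.add("maf", "variants", int(fail_maf.sum()),
               int((~fail_maf).sum()), threshold=maf_min)
    report.add("combined", "variants", int((~keep).sum()), int(keep.sum()))
    out = gm.take_variants(keep)
    report.n_samples_out = out.n_samples
    report.n_variants_out = out.n_variants
    return out, report


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def allele_count_tables(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant allele-count 2x2 cells (cases vs controls)."""
    labels = gm.samples["label"]
    cases = (labels == "case").to_numpy()
    controls = (labels == "control").to_numpy()
    if cases.sum() == 0 or controls.sum() == 0:
        raise GwasDataError("need at least one case and one control")

    def counts(mask):
        sub = gm.calls[mask]
        alt = np.nansum(sub, axis=0)
        n_called = np.sum(~np.isnan(sub), axis=0)
        return alt.astype(int), (2 * n_called - alt).astype(int)

    case_alt, case_ref = counts(cases)
    ctrl_alt, ctrl_ref = counts(controls)
    return pd.DataFrame(
        {
            "vid": gm.variants["vid"],
            "case_alt": case_alt,
            "case_ref": case_ref,
            "control_alt": ctrl_alt,
            "control_ref": ctrl_ref,
        }
    )


def allelic_fisher(gm: GenotypeMatrix) -> pd.DataFrame:
    """Two-sided Fisher exact test on the allele-count table of each variant.

    A variant with no non-missing calls in one group (or no variation at all)
    gets p = 1 and a ``degenerate`` flag.
    """
    tab = allele_count_tables(gm)
    ps = np.ones(len(tab))
    degenerate = np.zeros(len(tab), dtype=bool)
    for j, row in enumerate(tab.itertuples(index=False)):
        t = ContingencyTable2x2(row.case_alt, row.case_ref,
                                row.control_alt, row.control_ref)
        degenerate[j] = t.degenerate
        ps[j] = fisher_exact_p(t)
    out = gm.variants[["vid", "chrom", "pos"]].copy()
    out = out.merge(tab, on="vid")
    out["p_raw"] = ps
    out["degenerate"] = degenerate
    return out


def holm_adjust(p) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending (stable), multiply the k-th smallest by (m - k), enforce a
    running maximum, cap at 1, and restore the input order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(1.0, np.maximum.accumulate(adj))
    out = np.empty(m)
    out[order] = adj
    return out


def genomewide_threshold(m: int, alpha: float = 0.05) -> float:
    """Bonferroni genome-wide significance line alpha / m."""
    if m < 1:
        raise ValueError("need at least one test")
    return alpha / m


def _chrom_sort_key(chrom: str):
    try:
        return (0, CAT_CHROMOSOME_ORDER.index(str(chrom)), "")
    except ValueError:
        # natural-ish lexicographic fallback for non-feline chromosome names
        text = str(chrom)
        num = re.findall(r"\d+", text)
        return (1, int(num[0]) if num else 10**9, text)


def manhattan_qq_tables(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready Manhattan and QQ tables from an association frame.

    The Manhattan table is ordered by (chromosome in karyotype order,
    position) with a cumulative genome coordinate; the QQ table pairs sorted
    observed -log10 p with expected quantiles -log10((k - 0.5)/m).
    """
    if results.empty:
        raise ValueError("empty association results")
    df = results.copy()
    df["_key"] = df["chrom"].map(_chrom_sort_key)
    df = df.sort_values(["_key", "pos"], kind="stable").drop(columns="_key")
    df = df.reset_index(drop=True)
    offset, cum = {}, 0
    for chrom in df["chrom"].unique():
        offset[chrom] = cum
        cum += int(df.loc[df["chrom"] == chrom, "pos"].max()) + 1
    man = df[["vid", "chrom", "pos", "p_raw"]].copy()
    man["genome_pos"] = [
        offset[c] + p for c, p in zip(df["chrom"], df["pos"])
    ]
    man["neglog10_p"] = -np.log10(np.maximum(man["p_raw"], 1e-300))

    m = len(df)
    obs = np.sort(df["p_raw"].to_numpy())
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m),
            "observed": -np.log10(np.maximum(obs, 1e-300)),
        }
    )
    return man, qq


@dataclass
class AssociationResult:
    """Association table with raw and Holm-adjusted p, plus the QC trail."""

    table: pd.DataFrame
    qc: QcReport
    n_tests: int
    bonferroni: float

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "p_raw")


def run_association(
    gm: GenotypeMatrix,
    sample_call_rate: float = 0.95,
    variant_call_rate: float = 0.95,
    mendel_max: int = 1,
    maf_min: float = 0.05,
    alpha: float = 0.05,
) -> AssociationResult:
    """Full stage: sample QC -> variant QC -> exact tests -> Holm -> line."""
    gm1, report = sample_call_rate_filter(gm, sample_call_rate)
    gm2, report = variant_filters(gm1, variant_call_rate, mendel_max, maf_min,
                                  report)
    table = allelic_fisher(gm2)
    table["p_holm"] = holm_adjust(table["p_raw"].to_numpy())
    m = len(table)
    return AssociationResult(
        table=table, qc=report, n_tests=m,
        bonferroni=genomewide_threshold(m, alpha),
    )


def subset_rerun(
    gm: GenotypeMatrix, exclude, **qc_kwargs
) -> tuple[AssociationResult, pd.DataFrame]:
    """Re-run the whole pipeline on a sample subset and diff the top variants.

    ``exclude`` is either a predicate over sample rows (returning True for
    samples to drop) or an explicit list of sample ids.  Errors if the case
    or control group empties out.
    """
    if callable(exclude):
        drop = gm.samples.apply(exclude, axis=1).to_numpy(dtype=bool)
    else:
        drop = gm.samples["id"].isin(set(exclude)).to_numpy()
    sub = gm.take_samples(~drop)
    labels = sub.samples["label"]
    if (labels == "case").sum() == 0 or (labels == "control").sum() == 0:
        raise GwasDataError("exclusion emptied the case or control group")
    full_res = run_association(gm, **qc_kwargs)
    sub_res = run_association(sub, **qc_kwargs)
    merged = full_res.table[["vid", "p_raw", "p_holm"]].merge(
        sub_res.table[["vid", "p_raw", "p_holm"]],
        on="vid", suffixes=("_full", "_subset"),
    )
    merged["holm_change"] = merged["p_holm_subset"] - merged["p_holm_full"]
    changed = merged.sort_values("p_raw_subset").head(20).reset_index(drop=True)
    return sub_res, changed
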