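"""Ontogenetic statistics: age categories, nonparametric group tests,
inter-region ratios and PCA over cohort tables.

A cohort table holds one row per specimen with metadata columns
(``specimen_id``, ``species``, ``sex``, ``age_months``, ``age_category``)
and one column per parameter-region pair (``bvtv_base`` ...
``tb_n_epiphysis``; epiphysis columns are NaN when no secondary
ossification centre exists).  The analysis is nonparametric throughout —
a Shapiro-Wilk gate documents why — with Kruskal-Wallis omnibus tests
followed by Nemenyi post hoc comparisons over the five age categories,
run species-pooled and between species, plus Kruskal-Wallis tests on the
three inter-region ratios and two PCAs (base+metaphysis, and epiphysis
alone) via SVD of the scaled, centred data matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import CATEGORIES, PARAMS, REGIONS

ALPHA = 0.05

#: half-open age bins in months, youngest first
AGE_CATEGORIES: dict[str, tuple[float, float]] = {
    "Neonate": (0.0, 7.0),
    "Infant1": (7.0, 36.0),
    "Infant2": (36.0, 72.0),
    "Juvenile": (72.0, 144.0),
    "Adult": (144.0, math.inf),
}

RATIO_PAIRS = ("base_metaphysis", "base_epiphysis", "metaphysis_epiphysis")


def assign_age_category(age_months: float) -> str:
    """Age category from age in months.

    Bins are half-open on the right: [0, 7) Neonate, [7, 36) Infant1,
    [36, 72) Infant2, [72, 144) Juvenile, 144+ Adult (so exactly 12 years
    is Adult).  Negative ages raise.
    """
    if age_months < 0:
        raise ValueError("age_months must be >= 0")
    for name, (lo, hi) in AGE_CATEGORIES.items():
        if lo <= age_months < hi:
            return name
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# omnibus and post hoc tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: dict[str, np.ndarray] | list[np.ndarray],
                   ) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over groups.

    Requires >= 2 non-empty groups.  All-identical values are a valid
    degenerate case: H = 0, p = 1.
    """
    if isinstance(groups, dict):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    arrays = [a[np.isfinite(a)] for a in arrays]
    arrays = [a for a in arrays if a.size]
    if len(arrays) < 2:
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def nemenyi_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """All-pairs Nemenyi post hoc test after Kruskal-Wallis.

    Mean-rank differences are referred to the studentized-range
    distribution (infinite df), with the usual tie correction of the rank
    variance.  Returns a symmetric p-value matrix with unit diagonal.
    Groups with fewer than 2 observations get NaN rows/columns; the rest
    are computed.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    arrays = {k: a[np.isfinite(a)] for k, a in arrays.items()}
    usable = [k for k, a in arrays.items() if a.size >= 2]
    pooled = np.concatenate([arrays[k] for k in usable]) if usable else \
        np.array([])
    n = pooled.size
    k = len(usable)
    pmat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    np.fill_diagonal(pmat.values, 1.0)
    if k < 2:
        return pmat
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for key in usable:
        m = arrays[key].size
        mean_rank[key] = float(ranks[pos:pos + m].mean())
        sizes[key] = m
        pos += m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts ** 3 - counts).sum()) / (12.0 * (n - 1))
    a_var = n * (n + 1) / 12.0 - tie_term
    for i, gi in enumerate(usable):
        for gj in usable[i + 1:]:
            diff = abs(mean_rank[gi] - mean_rank[gj])
            se = math.sqrt(a_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if se == 0:
                p = 1.0
            else:
                q = diff / se * math.sqrt(2.0)
                p = float(sps.studentized_range.sf(q, k, np.inf))
            p = min(max(p, 0.0), 1.0)
            pmat.loc[gi, gj] = p
            pmat.loc[gj, gi] = p
    return pmat


def shapiro_gate(values: np.ndarray, alpha: float = ALPHA
                 ) -> tuple[float, float, bool, str]:
    """Shapiro-Wilk normality gate: (W, p, normal, flag).

    ``normal`` is False when p < alpha.  Fewer than 3 finite values or a
    constant vector is degenerate: the gate defaults to the nonparametric
    path (normal=False) with an explanatory flag.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 3:
        return math.nan, math.nan, False, "n < 3: defaulting to nonparametric"
    if np.all(v == v[0]):
        return math.nan, math.nan, False, "constant sample: degenerate"
    w, p = sps.shapiro(v)
    return float(w), float(p), bool(p >= alpha), ""


# ---------------------------------------------------------------------------
# ratios
# ---------------------------------------------------------------------------

@dataclass
class RatioRecord:
    """Per-variable inter-region ratios for one specimen.

    Orientation is fixed: base/metaphysis, base/epiphysis,
    metaphysis/epiphysis.  Ratios with a missing region or a zero
    denominator are NaN (flagged missing, never infinity).
    """

    ratios: dict[str, dict[str, float]]


def compute_ratios(record: pd.Series | dict) -> RatioRecord:
    """The three inter-region ratios for every trabecular variable."""
    get = record.get if isinstance(record, dict) else \
        (lambda k: record[k] if k in record else math.nan)
    out: dict[str, dict[str, float]] = {}
    present = 0
    for region in REGIONS:
        v = get(f"bvtv_{region}")
        if v is not None and np.isfinite(v):
            present += 1
    if present < 2:
        raise ValueError("need at least two regions with values")
    for p in PARAMS:
        vals = {}
        for pair in RATIO_PAIRS:
            num_r, den_r = pair.split("_", 1)
            num = get(f"{p}_{num_r}")
            den = get(f"{p}_{den_r}")
            num = math.nan if num is None else float(num)
            den = math.nan if den is None else float(den)
            if not (np.isfinite(num) and np.isfinite(den)) or den == 0:
                vals[pair] = math.nan
            else:
                vals[pair] = num / den
        out[p] = vals
    return RatioRecord(ratios=out)


def ratio_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level ratio columns ``{param}_{pair}`` (NaN where absent)."""
    rows = []
    for _, rec in cohort.iterrows():
        try:
            rr = compute_ratios(rec)
        except ValueError:
            rows.append({f"{p}_{pair}": math.nan for p in PARAMS
                         for pair in RATIO_PAIRS})
            continue
        rows.append({f"{p}_{pair}": rr.ratios[p][pair] for p in PARAMS
                     for pair in RATIO_PAIRS})
    out = pd.DataFrame(rows, index=cohort.index)
    for col in ("specimen_id", "age_category", "species"):
        if col in cohort:
            out[col] = cohort[col]
    return out


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAReport:
    """SVD-based PCA of the scaled, centred cohort matrix.

    ``loadings`` (variables x components) follow the deterministic sign
    convention that each loading vector's largest-magnitude entry is
    positive; ``proportion`` is the variance fraction per component;
    ``scores`` the per-specimen coordinates.
    """

    which: str
    loadings: pd.DataFrame
    proportion: np.ndarray
    scores: pd.DataFrame
    dropped: list[str] = field(default_factory=list)


def _pca_variables(which: str) -> list[str]:
    if which == "base_metaphysis":
        return [f"{p}_{r}" for r in ("base", "metaphysis") for p in PARAMS]
    if which == "epiphysis":
        return [f"{p}_epiphysis" for p in PARAMS]
    raise ValueError(f"unknown PCA variant {which!r}")


def run_pca(cohort: pd.DataFrame, which: str = "base_metaphysis"
            ) -> PCAReport:
    """PCA of a cohort over the variant's variable set.

    Complete-case rows only.  Columns are centred and scaled to unit
    sample variance; constant columns are dropped with a warning; with
    fewer rows than variables a warning is issued and only the available
    components are reported.
    """
    cols = _pca_variables(which)
    data = cohort[cols].dropna()
    if data.shape[0] < 3:
        raise ValueError(f"too few complete-case rows ({data.shape[0]}) "
                         f"for PCA {which!r}")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant columns from PCA: {dropped}")
    cols = [c for c, k in zip(cols, keep) if k]
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n, p = X.shape
    if n - 1 < p:
        warnings.warn(f"fewer rows ({n}) than variables ({p}): reporting "
                      f"{min(n - 1, p)} components")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    ncomp = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    U, S, Vt = U[:, :ncomp], S[:ncomp], Vt[:ncomp]
    # deterministic sign: largest-|.| entry of each loading positive
    for j in range(ncomp):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    var = S ** 2
    proportion = var / (X.shape[1] * (n - 1))
    pcs = [f"PC{j + 1}" for j in range(ncomp)]
    loadings = pd.DataFrame(Vt.T, index=cols, columns=pcs)
    scores = pd.DataFrame(U * S, index=data.index, columns=pcs)
    return PCAReport(which=which, loadings=loadings, proportion=proportion,
                     scores=scores, dropped=dropped)


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    """Bundle of all tables produced by :func:`run_study`."""

    shapiro: pd.DataFrame
    pooled_tests: pd.DataFrame
    pooled_posthoc: dict[tuple[str, str], pd.DataFrame]
    interspecific: pd.DataFrame
    ratio_tests: pd.DataFrame
    pca_base_metaphysis: PCAReport | None
    pca_epiphysis: PCAReport | None
    config: dict

    def write_csv(self, out_dir: str) -> None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.shapiro.to_csv(os.path.join(out_dir, "shapiro.csv"), index=False)
        self.pooled_tests.to_csv(
            os.path.join(out_dir, "pooled_tests.csv"), index=False)
        self.interspecific.to_csv(
            os.path.join(out_dir, "interspecific_tests.csv"), index=False)
        self.ratio_tests.to_csv(
            os.path.join(out_dir, "ratio_tests.csv"), index=False)
        for (param, region), mat in self.pooled_posthoc.items():
            mat.to_csv(os.path.join(out_dir,
                                    f"posthoc_{param}_{region}.csv"))
        for rep in (self.pca_base_metaphysis, self.pca_epiphysis):
            if rep is not None:
                rep.loadings.to_csv(
                    os.path.join(out_dir, f"pca_{rep.which}_loadings.csv"))
                rep.scores.to_csv(
                    os.path.join(out_dir, f"pca_{rep.which}_scores.csv"))


def _category_groups(df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    out = {}
    for cat in CATEGORIES:
        v = df.loc[df["age_category"] == cat, col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size:
            out[cat] = v
    return out


def run_study(
    cohort: pd.DataFrame,
    alpha: float = ALPHA,
    posthoc: bool = True,
    pca: bool = True,
    neonate_min: int = 3,
) -> StudyReport:
    """Run the full ontogenetic analysis on a cohort table.

    Per parameter and region: Shapiro-Wilk gate, species-pooled
    Kruskal-Wallis across age categories (with Nemenyi post hoc when
    ``posthoc``), and per-category interspecific Kruskal-Wallis tests
    (Neonate merged into Infant1 when either species has fewer than
    ``neonate_min`` Neonates).  Ratio variables are tested across age
    categories, and the two PCAs are run when ``pca``.  Empty cells are
    reported with an explicit note, never silently dropped.  Significance
    is assessed at ``alpha``.
    """
    if "age_category" not in cohort:
        cohort = cohort.copy()
        cohort["age_category"] = cohort["age_months"].map(assign_age_category)

    shapiro_rows, pooled_rows, inter_rows = [], [], []
    pooled_posthoc: dict[tuple[str, str], pd.DataFrame] = {}

    species = sorted(cohort["species"].dropna().unique()) \
        if "species" in cohort else []
    neonate_counts = [
        int(((cohort["age_category"] == "Neonate")
             & (cohort["species"] == sp)).sum()) for sp in species]
    merge_neonate = bool(neonate_counts) and min(neonate_counts) < neonate_min
    inter_cat = cohort["age_category"].copy()
    if merge_neonate:
        inter_cat = inter_cat.replace({"Neonate": "Infant1"})

    for p in PARAMS:
        for region in REGIONS:
            col = f"{p}_{region}"
            if col not in cohort:
                continue
            vals = cohort[col].to_numpy(dtype=float)
            w, sp_p, normal, flag = shapiro_gate(vals, alpha)
            shapiro_rows.append({"variable": col, "W": w, "p": sp_p,
                                 "normal": normal, "flag": flag})
            groups = _category_groups(cohort, col)
            if len(groups) < 2:
                pooled_rows.append({"parameter": p, "region": region,
                                    "H": math.nan, "p": math.nan,
                                    "significant": False,
                                    "note": "fewer than 2 age categories "
                                            "with data"})
                continue
            h, pval = kruskal_wallis(groups)
            pooled_rows.append({"parameter": p, "region": region, "H": h,
                                "p": pval, "significant": pval < alpha,
                                "note": ""})
            if posthoc:
                pooled_posthoc[(p, region)] = nemenyi_posthoc(groups)

            # interspecific comparison within each age category
            for cat in pd.unique(inter_cat):
                sub = cohort[inter_cat == cat]
                by_sp = [sub.loc[sub["species"] == s, col]
                         .dropna().to_numpy(dtype=float) for s in species]
                by_sp = [a for a in by_sp if a.size]
                row = {"parameter": p, "region": region, "category": cat,
                       "merged_neonate": merge_neonate and cat == "Infant1"}
                if len(by_sp) < 2:
                    row.update({"H": math.nan, "p": math.nan,
                                "significant": False,
                                "note": "a species has no data"})
                else:
                    h2, p2 = kruskal_wallis(by_sp)
                    row.update({"H": h2, "p": p2,
                                "significant": p2 < alpha, "note": ""})
                inter_rows.append(row)

    # ratios across age categories
    ratios = ratio_table(cohort)
    ratio_rows = []
    for p in PARAMS:
        for pair in RATIO_PAIRS:
            col = f"{p}_{pair}"
            groups = _category_groups(ratios, col)
            if len(groups) < 2:
                ratio_rows.append({"parameter": p, "ratio": pair,
                                   "H": math.nan, "p": math.nan,
                                   "significant": False,
                                   "note": "fewer than 2 age categories "
                                           "with data"})
                continue
            h, pval = kruskal_wallis(groups)
            ratio_rows.append({"parameter": p, "ratio": pair, "H": h,
                               "p": pval, "significant": pval < alpha,
                               "note": ""})

    pca_bm = pca_epi = None
    if pca:
        try:
            pca_bm = run_pca(cohort, "base_metaphysis")
        except ValueError as exc:
            warnings.warn(f"base+metaphysis PCA skipped: {exc}")
        try:
            pca_epi = run_pca(cohort, "epiphysis")
        except ValueError as exc:
            warnings.warn(f"epiphysis PCA skipped: {exc}")

    return StudyReport(
        shapiro=pd.DataFrame(shapiro_rows),
        pooled_tests=pd.DataFrame(pooled_rows),
        pooled_posthoc=pooled_posthoc,
        interspecific=pd.DataFrame(inter_rows),
        ratio_tests=pd.DataFrame(ratio_rows),
        pca_base_metaphysis=pca_bm,
        pca_epiphysis=pca_epi,
        config={"alpha": alpha, "posthoc": posthoc, "pca": pca,
                "neonate_min": neonate_min,
                "merged_neonate": merge_neonate},
    )
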