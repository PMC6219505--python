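"""Association and survival statistics for the cohort analyses.

Covers the statistical layer around the risk models: feature
preparation (mutation calls, arm-level copy-number dichotomization at
|0.10|, frequency and significance-score filters), 2x2 association
testing with the selection rule "chi-square unless any expected cell
count is below 5, then Fisher's exact test", Wilcoxon rank-sum and
Pearson tests, the MKI67/Ki-67 labeling-index calibration, Kaplan-Meier
curves with log-rank comparisons, and classical Cox proportional-
hazards fits.  All p-values are two-sided.

Standard tests are delegated to scipy and lifelines; the table
construction, selection rule and calibration logic live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .survnet import FeatureMatrix, SurvivalOutcome

__all__ = [
    "ContingencyTable",
    "TestResult",
    "CoxFit",
    "CalibrationFit",
    "FeaturePrepConfig",
    "dichotomize_arm_cna",
    "call_mutations",
    "prepare_features",
    "expected_counts",
    "select_test",
    "chi_square_test",
    "fisher_exact_test",
    "wilcoxon_rank_sum",
    "pearson_with_p",
    "calibrate_mki67",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "association_screen",
]


@dataclass
class ContingencyTable:
    """2x2 counts: a,b = group-1 positive/negative; c,d = group-2."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group1", "group2")
    col_labels: tuple[str, str] = ("positive", "negative")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TestResult:
    test: str
    p_two_sided: float
    statistic: float | None = None
    notes: str = ""


@dataclass
class CoxFit:
    """Classical Cox PH fit: per-covariate hazard ratios with Wald CIs."""

    table: pd.DataFrame  # index: covariate; columns: hr, ci_low, ci_high, p, se_log_hr
    adjusted_for: list[str] = field(default_factory=list)
    scaling_notes: dict[str, str] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    threshold: float
    r_squared: float
    target_index: float = 15.0
    fallback_used: bool = False


@dataclass
class FeaturePrepConfig:
    """Thresholds of the feature-preparation filters."""

    arm_cna_threshold: float = 0.10
    min_frequency: float = 0.05
    mutsig_p_threshold: float = 0.1
    gistic_p_threshold: float = 0.25
    mutsig_q_threshold: float = 0.05
    mki67_high_cutoff: float = 700.0

    def __post_init__(self) -> None:
        for name in ("arm_cna_threshold", "min_frequency", "mutsig_p_threshold",
                     "gistic_p_threshold", "mutsig_q_threshold", "mki67_high_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def dichotomize_arm_cna(arm_fractions, threshold: float = 0.10):
    """Classify signed arm-fraction values: gain iff value >= +threshold,
    loss iff value <= -threshold, else neutral."""
    arr = np.asarray(arm_fractions, dtype=float)
    if np.any(arr < -1) or np.any(arr > 1):
        raise ValueError("arm fractions must lie in [-1, 1]")
    out = np.where(arr >= threshold, "gain", np.where(arr <= -threshold, "loss", "neutral"))
    if isinstance(arm_fractions, pd.DataFrame):
        return pd.DataFrame(out, index=arm_fractions.index, columns=arm_fractions.columns)
    if isinstance(arm_fractions, pd.Series):
        return pd.Series(out, index=arm_fractions.index)
    return out if arr.ndim else out.item()


#: variant classes that change the amino-acid sequence and count as mutation calls
NONSILENT_CLASSES = {
    "missense", "nonsense", "frameshift", "splice_site", "in_frame_indel",
    "nonstop", "translation_start_site",
}


def call_mutations(variants: pd.DataFrame, sample_ids: list[str],
                   genes: list[str] | None = None) -> pd.DataFrame:
    """Dichotomous mutation calls from a long variant table.

    ``variants`` needs columns sample_id, gene, variant_class.  A sample
    is called mutant for a gene iff it carries at least one variant
    whose class changes the amino-acid sequence (silent/synonymous
    variants are not calls).
    """
    required = {"sample_id", "gene", "variant_class"}
    if not required <= set(variants.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    nonsilent = variants[variants["variant_class"].str.lower().isin(NONSILENT_CLASSES)]
    if genes is None:
        genes = sorted(variants["gene"].unique())
    calls = pd.DataFrame(0, index=list(sample_ids), columns=list(genes))
    for _, row in nonsilent.iterrows():
        if row["sample_id"] in calls.index and row["gene"] in calls.columns:
            calls.loc[row["sample_id"], row["gene"]] = 1
    return calls


def prepare_features(mutation_calls: pd.DataFrame | None = None,
                     arm_cna: pd.DataFrame | None = None,
                     continuous: pd.DataFrame | None = None,
                     mutsig_scores: pd.DataFrame | None = None,
                     gistic_p: pd.Series | None = None,
                     config: FeaturePrepConfig | None = None,
                     continuous_kind: str = "protein",
                     ) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Assemble the model's feature matrix from raw tables.

    Mutation calls become 0/1 columns, filtered by MutSig q <= threshold
    (when scores are supplied) and by cohort frequency.  Arm-level
    copy-number fractions are dichotomized at |0.10| into separate
    gain/loss indicator columns, filtered by GISTIC p and frequency.
    Continuous columns (protein, expression, clinical) pass through
    unfiltered.  Returns the matrix and a log of dropped features.
    """
    config = config or FeaturePrepConfig()
    blocks: list[pd.DataFrame] = []
    kinds: list[str] = []
    dropped: list[dict] = []
    index = None
    for df in (mutation_calls, arm_cna, continuous):
        if df is not None:
            if index is None:
                index = df.index
            elif not index.equals(df.index):
                raise ValueError("sample ids do not match across input tables")
    if index is None:
        raise ValueError("no input tables supplied")

    if mutation_calls is not None:
        muts = mutation_calls.astype(float)
        if not muts.isin([0.0, 1.0]).all().all():
            raise ValueError("mutation calls must be 0/1")
        for gene in muts.columns:
            if mutsig_scores is not None and gene in mutsig_scores.index:
                q = mutsig_scores.loc[gene].get("q", np.nan)
                p = mutsig_scores.loc[gene].get("p", np.nan)
                if np.isfinite(q) and q > config.mutsig_q_threshold:
                    dropped.append({"feature": gene, "reason": "mutsig_q"})
                    continue
                if np.isfinite(p) and p > config.mutsig_p_threshold:
                    dropped.append({"feature": gene, "reason": "mutsig_p"})
                    continue
            freq = muts[gene].mean()
            if freq < config.min_frequency:
                dropped.append({"feature": gene, "reason": "frequency"})
                continue
            blocks.append(muts[[gene]])
            kinds.append("mutation")

    if arm_cna is not None:
        calls = dichotomize_arm_cna(arm_cna, config.arm_cna_threshold)
        for arm in arm_cna.columns:
            if gistic_p is not None and arm in gistic_p.index \
                    and gistic_p[arm] > config.gistic_p_threshold:
                dropped.append({"feature": arm, "reason": "gistic_p"})
                continue
            for direction in ("gain", "loss"):
                col = (calls[arm] == direction).astype(float)
                name = f"{arm}_{direction}"
                freq = col.mean()
                if freq == 0:
                    continue
                if freq < config.min_frequency:
                    dropped.append({"feature": name, "reason": "frequency"})
                    continue
                blocks.append(col.to_frame(name))
                kinds.append("cna_arm")

    if continuous is not None:
        blocks.append(continuous.astype(float))
        kinds.extend([continuous_kind] * continuous.shape[1])

    if not blocks:
        raise ValueError("no features survived preparation")
    mat = pd.concat(blocks, axis=1)
    fm = FeatureMatrix(mat.to_numpy(float), list(mat.columns),
                       [str(i) for i in mat.index], kinds)
    return fm, pd.DataFrame(dropped, columns=["feature", "reason"])


def expected_counts(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence: row x col totals / N."""
    t = table.as_array()
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / table.n


def select_test(table: ContingencyTable) -> str:
    """'fisher_exact' iff any expected cell count is below 5, else
    'chi_square'."""
    return "fisher_exact" if expected_counts(table).min() < 5 else "chi_square"


def chi_square_test(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction,
    1 degree of freedom."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined with a zero marginal")
    stat = n * (a * d - b * c) ** 2 / margins
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult("chi_square", p, float(stat))


def fisher_exact_test(table: ContingencyTable) -> TestResult:
    """Fisher's exact test, two-sided by the probability-mass rule (sum of
    hypergeometric probabilities no larger than the observed table's)."""
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return TestResult("fisher_exact", float(p))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney): exact distribution for
    combined n <= 20 without ties, normal approximation with tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return TestResult("wilcoxon", 1.0, notes="all values identical")
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("wilcoxon", float(res.pvalue), float(res.statistic),
                      notes=method)


def pearson_with_p(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 aligned pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one variable")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(p), float(r))


def calibrate_mki67(pairs: pd.DataFrame, target_index: float = 15.0,
                    fallback_cutoff: float = 700.0) -> CalibrationFit:
    """Regress Ki-67 labeling index on MKI67 expression and invert the
    line at ``target_index`` to get the 'high expression' cutoff.

    A (near-)zero slope makes the inversion meaningless; the fixed
    cutoff is then used and flagged.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 calibration pairs")
    res = sps.linregress(pairs["expression"], pairs["labeling_index"])
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2)
    if slope == 0 or not np.isfinite(slope):
        return CalibrationFit(slope, intercept, fallback_cutoff, r2,
                              target_index, fallback_used=True)
    return CalibrationFit(slope, intercept, (target_index - intercept) / slope,
                          r2, target_index)


def km_estimate(outcomes: SurvivalOutcome) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier product-limit curve and median survival.

    The median is the earliest time the curve drops to <= 0.5; NaN when
    it never does.
    """
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(outcomes.time, outcomes.event)
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    surv = curve[curve["survival"] <= 0.5]
    median = float(surv["time"].iloc[0]) if len(surv) else float("nan")
    return curve, median


def logrank_test(outcomes: SurvivalOutcome, groups) -> TestResult:
    """Two-group log-rank test (observed minus expected over pooled event
    times; chi-square with 1 df)."""
    from lifelines.statistics import logrank_test as ll_logrank

    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("log-rank comparison needs exactly 2 groups")
    m0, m1 = groups == levels[0], groups == levels[1]
    if outcomes.event[m0].sum() + outcomes.event[m1].sum() == 0:
        raise ValueError("no events in either group")
    res = ll_logrank(outcomes.time[m0], outcomes.time[m1],
                     event_observed_A=outcomes.event[m0],
                     event_observed_B=outcomes.event[m1])
    return TestResult("logrank", float(res.p_value), float(res.test_statistic))


def cox_fit(covariates: pd.DataFrame, outcomes: SurvivalOutcome,
            adjust_for: list[str] | None = None,
            scaling: dict[str, float] | None = None) -> CoxFit:
    """Classical Cox proportional-hazards fit (Breslow ties) via Newton
    iterations on the partial likelihood.

    ``scaling`` rescales covariates before fitting so the hazard ratio
    is per chosen unit (e.g. ``{"age": 10}`` for per-decade, or log2-
    transformed expression so the HR is per doubling).  ``adjust_for``
    lists covariates included as adjustment terms; the returned table
    covers every fitted covariate.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    adjust_for = adjust_for or []
    missing = set(adjust_for) - set(covariates.columns)
    if missing:
        raise ValueError(f"adjustment covariates absent: {sorted(missing)}")
    X = covariates.astype(float).copy()
    notes = {}
    for col, unit in (scaling or {}).items():
        X[col] = X[col] / unit
        notes[col] = f"per {unit} units"
    n_events = int(outcomes.event.sum())
    if n_events < X.shape[1]:
        raise ValueError("fewer events than covariates")
    df = X.copy()
    df["time"] = outcomes.time
    df["event"] = outcomes.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
        "se_log_hr": s["se(coef)"],
        "log_hr": s["coef"],
    })
    return CoxFit(table, adjust_for, notes, n=len(outcomes), n_events=n_events)


def association_screen(features: FeatureMatrix, labels) -> pd.DataFrame:
    """Per-feature 2x2 association against a binary label.

    Builds the (feature+/-, label+/-) table for every binary feature,
    applies the expected-count test-selection rule, and reports counts,
    the test used and its two-sided p, sorted ascending by p.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != features.n_samples:
        raise ValueError("labels not aligned with features")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    rows = []
    for j, name in enumerate(features.feature_names):
        x = features.values[:, j]
        if not np.all(np.isin(x, (0.0, 1.0))):
            continue  # screen applies to binary alterations only
        a = int(np.sum((x == 1) & (labels == 1)))
        b = int(np.sum((x == 1) & (labels == 0)))
        c = int(np.sum((x == 0) & (labels == 1)))
        d = int(np.sum((x == 0) & (labels == 0)))
        table = ContingencyTable(a, b, c, d)
        test = select_test(table)
        result = (chi_square_test if test == "chi_square" else fisher_exact_test)(table)
        rows.append({"feature": name, "pos_label_pos": a, "pos_label_neg": b,
                     "neg_label_pos": c, "neg_label_neg": d,
                     "test": test, "p": result.p_two_sided})
    out = pd.DataFrame(rows)
    return out.sort_values("p", kind="stable").reset_index(drop=True)
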