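"""Statistical machinery for the phase comparison and playback scoring.

* Permuted discriminant function analysis (pDFA): a two-class Fisher
  discriminant whose classification-count statistic is tested by
  restricted permutation — phase labels are reshuffled *within* each
  individual, so individuality is controlled as a random factor.
* Exact / Monte-Carlo two-tailed paired permutation tests (sign flips of
  per-pair differences).
* Within-subject comparison via balanced block ANOVA (subject as block):
  F = MS_effect / MS_(effect x subject), the repeated-measures analogue
  of a GLM with a random subject factor.
* Playback-response scoring: de-duplication of perfectly correlated or
  degenerate measures, PCA on the correlation matrix with the
  eigenvalue > 1 retention rule, and Wilcoxon signed-rank follow-ups
  with an exact small-sample distribution.

Monte-Carlo p-values use the add-one correction
p = (1 + #{null >= observed}) / (1 + N), so the attainable floor at
N permutations is 1/(N+1) and p = 0 never occurs.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "LDAResult",
    "PDFAResult",
    "PCScores",
    "fisher_lda",
    "pdfa_crossed",
    "paired_permutation_test",
    "within_subject_phase_test",
    "normality_screen",
    "dedup_measures",
    "response_pca",
    "wilcoxon_signed_rank",
    "playback_analysis",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDAResult:
    axis: np.ndarray  # discriminant direction in feature space
    coefficients: dict[str, float]  # standardized discriminant coefficients
    predicted: np.ndarray  # predicted class label per row
    n_correct: int
    n_total: int


@dataclass(frozen=True)
class PDFAResult:
    n_correct: int
    n_total: int
    p_value: float
    n_permutations: int
    discriminant_coefficients: dict[str, float]
    excluded_parameters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.n_correct <= self.n_total
        assert self.p_value >= 1.0 / (self.n_permutations + 1) - 1e-12


@dataclass(frozen=True)
class PCScores:
    eigenvalues: np.ndarray  # all eigenvalues, descending
    retained: tuple[int, ...]  # indices of components with eigenvalue > 1
    variance_fraction: np.ndarray  # per retained component
    loadings: pd.DataFrame  # measures x retained components (unit eigenvectors)
    scores: pd.DataFrame  # trials x retained components
    unstable_retention: bool = False  # eigenvalues hovering at 1


def _class_matrix(
    table: pd.DataFrame, columns: list[str], class_col: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = table[columns].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("feature table contains missing values in used columns")
    y = table[class_col].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    return x, y, classes


def fisher_lda(
    table: pd.DataFrame,
    columns: list[str],
    class_col: str = "phase",
    ridge: float = 1e-8,
) -> LDAResult:
    """Two-class Fisher discriminant with nearest-centroid classification.

    The axis w = Sw^-1 (m1 - m0) maximizes the between/within variance
    ratio; each row is assigned to the class whose projected centroid is
    nearer.  ``ridge`` scales an identity added to the pooled within-class
    covariance (relative to its mean diagonal) so near-singular tables
    still yield an axis; standardized coefficients (axis * pooled
    within-class SD) indicate each parameter's discriminative weight.
    """
    x, y, classes = _class_matrix(table, columns, class_col)
    masks = [y == c for c in classes]
    if min(m.sum() for m in masks) < 2:
        raise ValueError("need >= 2 rows per class")
    means = [x[m].mean(axis=0) for m in masks]
    sw = sum(np.cov(x[m], rowvar=False) * (m.sum() - 1) for m in masks)
    sw /= len(x) - 2
    sw = np.atleast_2d(sw)
    scale = np.mean(np.diag(sw)) if np.any(np.diag(sw) > 0) else 1.0
    try:
        axis = np.linalg.solve(sw + ridge * scale * np.eye(len(columns)), means[1] - means[0])
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; increase ridge"
        ) from err
    proj = x @ axis
    centroids = [proj[m].mean() for m in masks]
    predicted = np.where(
        np.abs(proj - centroids[0]) <= np.abs(proj - centroids[1]), classes[0], classes[1]
    )
    within_sd = np.sqrt(np.diag(sw))
    coeffs = dict(zip(columns, axis * within_sd))
    return LDAResult(
        axis=axis,
        coefficients=coeffs,
        predicted=predicted,
        n_correct=int((predicted == y).sum()),
        n_total=len(y),
    )


def normality_screen(
    table: pd.DataFrame,
    columns: list[str],
    class_col: str = "phase",
    subject_col: str = "individual_id",
    alpha: float = 0.05,
) -> dict[str, float]:
    """Shapiro-Wilk p-values on pooled residuals (cell means removed).

    Advisory: parameters failing at ``alpha`` are logged as candidates for
    exclusion from the discriminant analysis, which assumes normality;
    actual exclusion is the caller's explicit choice.
    """
    out = {}
    for col in columns:
        resid = (
            table[col]
            - table.groupby([subject_col, class_col], sort=False)[col].transform("mean")
        ).to_numpy()
        if np.ptp(resid) == 0:
            # degenerate residuals (e.g. quantized measurements identical
            # within every cell): decidedly non-normal
            out[col] = 0.0
            log.info("normality screen: %s has zero-range residuals", col)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(scipy.stats.shapiro(resid).pvalue)
        out[col] = p
        if p < alpha:
            log.info("normality screen: %s has Shapiro-Wilk p=%.3g < %g", col, p, alpha)
    return out


def _check_crossed(y: np.ndarray, subjects: np.ndarray) -> None:
    for s in np.unique(subjects):
        if len(np.unique(y[subjects == s])) < 2:
            raise ValueError(f"individual {s!r} observed in only one phase (design not crossed)")


def pdfa_crossed(
    table: pd.DataFrame,
    columns: list[str],
    class_col: str = "phase",
    subject_col: str = "individual_id",
    n_permutations: int = 1000,
    seed: int = 0,
    exclude: tuple[str, ...] = (),
) -> PDFAResult:
    """Permuted DFA with the individual as a crossed random factor.

    The observed statistic is the number of rows correctly classified by
    the Fisher discriminant.  The null distribution reassigns the phase
    labels at random *within each individual* (preserving the per-phase
    counts of that individual) and re-runs the full DFA; the p-value is
    (1 + #{permuted >= observed}) / (1 + n_permutations).
    """
    used = [c for c in columns if c not in exclude]
    x_cols = used
    y = table[class_col].to_numpy()
    subjects = table[subject_col].to_numpy()
    _check_crossed(y, subjects)
    observed = fisher_lda(table, x_cols, class_col)
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(subjects == s) for s in np.unique(subjects)]
    perm_table = table.copy()
    count_ge = 0
    y_perm = y.copy()
    for _ in range(n_permutations):
        for idx in groups:
            y_perm[idx] = y[idx][rng.permutation(len(idx))]
        perm_table[class_col] = y_perm
        stat = fisher_lda(perm_table, x_cols, class_col).n_correct
        if stat >= observed.n_correct:
            count_ge += 1
    p = (1 + count_ge) / (1 + n_permutations)
    return PDFAResult(
        n_correct=observed.n_correct,
        n_total=observed.n_total,
        p_value=p,
        n_permutations=n_permutations,
        discriminant_coefficients=observed.coefficients,
        excluded_parameters=tuple(exclude),
    )


def paired_permutation_test(
    x,
    y,
    n_mc: int = 10000,
    mode: str = "auto",
    seed: int = 0,
    exact_cap: int = 2**20,
) -> float:
    """Two-tailed paired permutation test on the mean of differences.

    The null randomly flips the sign of each pair's difference.  In exact
    mode all 2^n sign patterns are enumerated; in Monte-Carlo mode
    ``n_mc`` random patterns are drawn and the add-one correction applied.
    ``mode="auto"`` enumerates exactly whenever 2^n <= ``exact_cap``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    if n < 2 or len(np.asarray(y)) != n:
        raise ValueError("need paired samples of equal length n >= 2")
    if np.all(d == 0):
        return 1.0
    observed = abs(d.mean())
    if mode not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" and 2**n > exact_cap:
        raise ValueError(f"exact mode infeasible: 2^{n} > cap {exact_cap}")
    if mode == "exact" or (mode == "auto" and 2**n <= exact_cap):
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        stats = np.abs(signs @ d) / n
        return float(np.mean(stats >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    signs = rng.choice((1.0, -1.0), size=(n_mc, n))
    stats = np.abs(signs @ d) / n
    return float((1 + np.sum(stats >= observed - 1e-12)) / (1 + n_mc))


def within_subject_phase_test(
    table: pd.DataFrame,
    parameter: str,
    class_col: str = "phase",
    subject_col: str = "individual_id",
) -> tuple[float, float]:
    """Repeated-measures one-way test of a parameter across phases.

    Replicate observations within a subject x phase cell are averaged,
    then F = MS_phase / MS_(phase x subject) with df (p-1, (p-1)(s-1)) —
    the classical randomized-block analysis, equivalent to a GLM with
    phase fixed and subject as a random factor for this balanced design.
    Returns (F, p).
    """
    cell = table.groupby([subject_col, class_col], sort=True)[parameter].mean().unstack()
    if cell.isna().any().any():
        raise ValueError("design not crossed: some subject lacks a phase")
    s, p = cell.shape
    if s < 3:
        raise ValueError("need at least 3 subjects")
    values = cell.to_numpy()
    grand = values.mean()
    phase_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_phase = s * np.sum((phase_means - grand) ** 2)
    resid = values - subj_means[:, None] - phase_means[None, :] + grand
    ss_err = np.sum(resid**2)
    df1, df2 = p - 1, (p - 1) * (s - 1)
    ms_phase = ss_phase / df1
    ms_err = ss_err / df2
    # guard against 0/0 float dust when the data are exactly degenerate
    tiny = 1e-12 * max(float(np.sum((values - grand) ** 2)), 1e-300)
    if ss_phase <= tiny:
        return 0.0, 1.0
    if ms_err <= tiny:
        return np.inf, 0.0
    f = ms_phase / ms_err
    return float(f), float(scipy.stats.f.sf(f, df1, df2))


def dedup_measures(
    table: pd.DataFrame,
    measures: list[str] | None = None,
    r_tol: float = 1e-12,
    var_tol: float = 1e-12,
    count_floor: float | None = None,
    count_columns: tuple[str, ...] = ("n_calls",),
) -> tuple[pd.DataFrame, list[str]]:
    """Drop duplicated and degenerate response measures before the PCA.

    For every pair of measures correlating at |r| = 1 (within ``r_tol``)
    the later column is dropped; near-zero-variance columns are dropped;
    count columns whose total falls below ``count_floor`` (rare events —
    e.g. a handful of calls across all playbacks) are dropped.  Returns
    the reduced table and a log of dropped columns with reasons.
    """
    if measures is None:
        measures = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
                    and c not in ("order",)]
    if len(table) < 3:
        raise ValueError("need at least 3 trials")
    dropped: list[str] = []
    keep: list[str] = []
    for col in measures:
        v = table[col].to_numpy(dtype=float)
        if np.var(v) <= var_tol:
            dropped.append(f"{col}: zero variance")
            continue
        if count_floor is not None and col in count_columns and v.sum() < count_floor:
            dropped.append(f"{col}: total count {v.sum():g} below floor {count_floor:g}")
            continue
        dup = None
        for prev in keep:
            r = np.corrcoef(table[prev].to_numpy(dtype=float), v)[0, 1]
            if abs(abs(r) - 1.0) <= r_tol:
                dup = prev
                break
        if dup is not None:
            dropped.append(f"{col}: |r| = 1 with {dup}")
            continue
        keep.append(col)
    for msg in dropped:
        log.info("dedup_measures: dropped %s", msg)
    return table[[c for c in table.columns if c not in measures or c in keep]], dropped


def response_pca(table: pd.DataFrame, measures: list[str] | None = None) -> PCScores:
    """PCA on the correlation matrix of the (de-duplicated) measures.

    Measures are standardized; components with eigenvalue > 1 are
    retained; each retained component's unit-eigenvector loadings are
    sign-fixed so the largest-magnitude loading is positive, and per-trial
    scores are the projections of the standardized data.
    """
    if measures is None:
        measures = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
                    and c not in ("order",)]
    if len(measures) < 2:
        raise ValueError("need at least 2 measures")
    if len(table) < 3:
        raise ValueError("need at least 3 trials")
    x = table[measures].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [m for m, s in zip(measures, sd) if s == 0]
        raise ValueError(f"constant column(s) {bad}; run dedup_measures first")
    z = (x - x.mean(axis=0)) / sd
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    retained = tuple(int(i) for i in np.flatnonzero(eigval > 1.0))
    unstable = bool(np.any(np.abs(eigval - 1.0) < 0.05))
    if unstable:
        log.info("response_pca: eigenvalues near 1.0; retention may be unstable")
    load = eigvec[:, list(retained)].copy()
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1
    names = [f"PC{i + 1}" for i in retained]
    return PCScores(
        eigenvalues=eigval,
        retained=retained,
        variance_fraction=eigval[list(retained)] / len(measures),
        loadings=pd.DataFrame(load, index=measures, columns=names),
        scores=pd.DataFrame(z @ load, index=table.index, columns=names),
        unstable_retention=unstable,
    )


def _wilcoxon_exact_sf(ranks2: np.ndarray, w2: float) -> float:
    """P(W >= w) for the signed-rank sum under random signs, by convolution.

    ``ranks2`` are the (mid-)ranks doubled to integers; ``w2`` is the
    doubled statistic.  The distribution of the positive-rank sum is
    built by dynamic programming over the 2^n equiprobable sign patterns.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * dist + 0.5 * shifted
    start = int(np.ceil(w2 - 1e-9))
    return float(dist[start:].sum())


def wilcoxon_signed_rank(x, y, exact_n: int = 25) -> tuple[float, float]:
    """Two-tailed Wilcoxon matched-pairs signed-rank test.

    Zero differences are dropped; ties get mid-ranks.  For n <= ``exact_n``
    the p-value comes from the exact distribution of the positive-rank sum
    W+ (computed by convolution, valid with mid-ranks); larger samples use
    the normal approximation with tie correction.  Returns (W+, p); the
    printed statistic is the positive-rank sum, and the matching normal
    deviate is ``(W+ - n(n+1)/4) / sd``.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    if n <= exact_n:
        # the sign-flip distribution of W+ is symmetric about total/2
        # (flipping every sign maps W+ to total - W+), so the two-tailed
        # p is twice the upper tail at max(W+, W-)
        ranks2 = np.round(2 * ranks).astype(int)
        p = min(1.0, 2.0 * _wilcoxon_exact_sf(ranks2, 2 * max(w_plus, w_minus)))
    else:
        mean = n * (n + 1) / 4
        tie_term = np.sum(np.array([np.sum(ranks == r) for r in np.unique(ranks)]) ** 3
                          - np.array([np.sum(ranks == r) for r in np.unique(ranks)])) / 48
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
        z = (w_plus - mean) / sd
        p = float(2 * scipy.stats.norm.sf(abs(z)))
    return w_plus, float(min(p, 1.0))


def playback_analysis(
    scores: PCScores,
    table: pd.DataFrame,
    stimulus_col: str = "stimulus",
    order_col: str = "order",
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Within-subject tests of each retained PC against stimulus type and order.

    Subjects missing one stimulus type are excluded with a warning.
    Returns one row per retained component with (F, p) for the stimulus
    type and for the presentation order.
    """
    data = table.copy()
    data = data.join(scores.scores)
    counts = data.groupby(subject_col)[stimulus_col].nunique()
    incomplete = counts[counts < 2].index
    if len(incomplete):
        log.warning("excluding subjects missing a stimulus type: %s", list(incomplete))
        data = data[~data[subject_col].isin(incomplete)]
    rows = []
    for pc in scores.scores.columns:
        f_t, p_t = within_subject_phase_test(data, pc, class_col=stimulus_col,
                                             subject_col=subject_col)
        f_o, p_o = within_subject_phase_test(data, pc, class_col=order_col,
                                             subject_col=subject_col)
        rows.append({"component": pc, "F_stimulus": f_t, "p_stimulus": p_t,
                     "F_order": f_o, "p_order": p_o})
    return pd.DataFrame(rows)
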