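"""Inference machinery: permutation tests, accuracy transforms,
repeated-measures ANOVA with Greenhouse-Geisser correction, polynomial
contrasts, and the two-stage aggregation of answer-run proportions.

Accuracy proportions are edge-corrected, (correct - 0.5) / total, before a
logit transform so perfect scores map to finite values. Classification
significance uses a stratified permutation scheme: condition labels are
re-shuffled within each run (preserving the design's per-run class
balance), the full cross-validation is re-run, and the p-value is
(#{null error <= observed error} + 1) / (n_permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decode import DecodingResult, SvmConfig, cv_leave_one_run_out
from .features import TrialFeatures


# ---------------------------------------------------------------------------
# accuracy transforms


def edge_corrected_proportion(correct: int, total: int) -> float:
    """(correct - 0.5) / total; keeps the logit finite at 100% accuracy."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie in [0, total]")
    return (correct - 0.5) / total

def logit(p: float) -> float:
    """Natural log-odds of a proportion strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit undefined for p={p}")
    return float(np.log(p / (1.0 - p)))


# ---------------------------------------------------------------------------
# permutation inference


@dataclass(frozen=True)
class PermConfig:
    """Permutation-test settings.

    ``stratify_by_run`` shuffles labels within each run, preserving the
    per-run class balance of the design; switching it off permutes labels
    across the whole feature set.
    """

    n_perm: int = 2000
    seed: int = 0
    stratify_by_run: bool = True

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")


@dataclass
class PermResult:
    observed_error: float
    null_errors: np.ndarray
    p: float
    null_mean: float
    null_ci95: tuple[float, float]

    @property
    def observed_accuracy(self) -> float:
        return 1.0 - self.observed_error


def permute_labels_within_runs(
    y: np.ndarray, run_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independent label shuffle inside every run (class counts kept)."""
    out = np.array(y)
    for run in np.unique(run_ids):
        idx = np.flatnonzero(run_ids == run)
        out[idx] = out[idx][rng.permutation(idx.size)]
    return out


def permutation_test(
    features: TrialFeatures,
    cv_scheme: Callable[[TrialFeatures], DecodingResult] | None = None,
    cfg: PermConfig | None = None,
    svm_cfg: SvmConfig | None = None,
) -> PermResult:
    """Permutation null of the cross-validated classification error.

    For each permutation the labels are re-assigned (within runs when
    stratified), the full CV is re-run, and the error recorded. The
    p-value adds one to numerator and denominator so it can never be zero;
    its floor is 1 / (n_perm + 1). The reported null band is the empirical
    central 95% interval.
    """
    cfg = cfg or PermConfig()
    if cfg.n_perm < 19:
        warnings.warn(
            f"n_perm={cfg.n_perm} cannot resolve p < 0.05", stacklevel=2
        )
    scheme = cv_scheme or (lambda f: cv_leave_one_run_out(f, svm_cfg))
    observed = scheme(features).error
    rng = np.random.default_rng(cfg.seed)
    null_errors = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        if cfg.stratify_by_run:
            perm_y = permute_labels_within_runs(features.y, features.run_ids, rng)
        else:
            perm_y = features.y[rng.permutation(features.y.size)]
        null_errors[i] = scheme(features.with_labels(perm_y)).error
    k = int(np.sum(null_errors <= observed + 1e-12))
    p = (k + 1) / (cfg.n_perm + 1)
    lo, hi = np.percentile(null_errors, [2.5, 97.5])
    return PermResult(
        observed_error=float(observed),
        null_errors=null_errors,
        p=float(p),
        null_mean=float(null_errors.mean()),
        null_ci95=(float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


@dataclass
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    df1_gg: float
    df2_gg: float
    p_gg: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(e) for e in self.effects.values()]
        ).set_index("name")


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """A (k-1) x k orthonormal basis of the between-level contrast space."""
    # Helmert-style, then orthonormalised for numerical safety
    C = np.zeros((k - 1, k))
    for i in range(k - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    return C


def _gg_epsilon(Yc: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from contrast-space scores (n x d)."""
    d = Yc.shape[1]
    if d == 1:
        return 1.0
    S = np.cov(Yc, rowvar=False)
    tr = np.trace(S)
    tr2 = np.trace(S @ S)
    return float(tr**2 / (d * tr2))


def rm_anova(data: np.ndarray, factors: list[tuple[str, int]]) -> AnovaResult:
    """Fully within-subject ANOVA on a subjects x cells score matrix.

    ``factors`` lists (name, n_levels) with the first factor varying
    slowest across the cell columns. Each main effect and interaction gets
    the classical univariate F with its own subject-by-effect error term,
    plus the Greenhouse-Geisser epsilon estimated from the covariance of
    the contrast-transformed scores (exactly 1 for 2-level effects) and
    GG-adjusted p-value. Missing cells are not imputed.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x cells")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    n, n_cells = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    ks = [k for _, k in factors]
    if int(np.prod(ks)) != n_cells:
        raise ValueError(
            f"cells ({n_cells}) do not match factor levels {ks}"
        )

    bases = {}  # per factor: (contrast part, mean part)
    for name, k in factors:
        bases[name] = (_orthonormal_contrasts(k), np.full((1, k), 1 / np.sqrt(k)))

    effects: dict[str, EffectResult] = {}
    n_factors = len(factors)
    for pattern in range(1, 2**n_factors):
        members = [i for i in range(n_factors) if pattern >> i & 1]
        name = " x ".join(factors[i][0] for i in members)
        C = np.ones((1, 1))
        for i, (fname, k) in enumerate(factors):
            part = bases[fname][0] if i in members else bases[fname][1]
            C = np.kron(C, part)
        Yc = data @ C.T  # n x df_effect
        df1 = Yc.shape[1]
        col_means = Yc.mean(axis=0)
        ss_eff = n * float(np.sum(col_means**2))
        ss_err = float(np.sum((Yc - col_means) ** 2))
        df2 = (n - 1) * df1
        if ss_err == 0:
            # degenerate (e.g. ceiling) data: no subject-by-effect variance
            warnings.warn(
                f"zero error variance for effect {name!r}", stacklevel=2
            )
            F = np.inf if ss_eff > 0 else np.nan
            eps = 1.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
            eps = _gg_epsilon(Yc)
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else (
            0.0 if F == np.inf else np.nan
        )
        p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else p
        effects[name] = EffectResult(
            name=name,
            F=float(F),
            df1=float(df1),
            df2=float(df2),
            p=p,
            gg_epsilon=eps,
            df1_gg=float(df1 * eps),
            df2_gg=float(df2 * eps),
            p_gg=p_gg,
            ss_effect=ss_eff,
            ss_error=ss_err,
        )
    return AnovaResult(effects=effects)


def polynomial_contrast_weights(k: int) -> np.ndarray:
    """Orthonormal polynomial contrasts (orders 1..k-1) for k equally
    spaced levels; pairwise orthogonal rows of unit norm."""
    x = np.arange(k, dtype=float)
    V = np.vander(x, k, increasing=True)  # columns 1, x, x^2, ...
    Q, _ = np.linalg.qr(V)
    W = Q[:, 1:].T  # drop the constant column
    # fix sign: leading coefficient positive (increasing linear trend > 0)
    for row in W:
        if row[-1] < 0:
            row *= -1
    return W


_ORDER_NAMES = ["linear", "quadratic", "cubic", "quartic", "quintic"]


def polynomial_contrasts(data: np.ndarray) -> pd.DataFrame:
    """Planned within-subject polynomial trend tests over factor levels.

    ``data`` is subjects x levels (equal spacing assumed). Each order's
    per-subject contrast score is tested against zero with a one-sample F
    (t squared, df = (1, n - 1)).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need at least 2 levels")
    W = polynomial_contrast_weights(k)
    tol = 1e-10 * max(1.0, float(np.abs(data).max()))
    rows = []
    for order, w in enumerate(W, start=1):
        scores = data @ w
        mean = scores.mean()
        var = scores.var(ddof=1)
        if abs(mean) < tol and var < tol**2:
            mean, var = 0.0, 0.0
        if var == 0:
            F = 0.0 if mean == 0 else np.inf
        else:
            F = n * mean**2 / var
        p = float(sps.f.sf(F, 1, n - 1)) if np.isfinite(F) else 0.0
        name = (
            _ORDER_NAMES[order - 1]
            if order <= len(_ORDER_NAMES)
            else f"order-{order}"
        )
        rows.append({"order": order, "name": name, "F": float(F), "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# answer-table aggregation


def aggregate_answer_table(
    answers: pd.DataFrame,
    value_cols: list[str] | None = None,
    subject_col: str = "subject",
) -> pd.DataFrame:
    """Two-stage mean of answer-run proportions per training-size column.

    Proportions are first averaged within subject (over that subject's
    answer runs) and then across subjects; the across-subject SD is
    reported alongside. This is the aggregation that reproduces an overall
    row from per-run proportions.
    """
    if value_cols is None:
        value_cols = [
            c for c in answers.columns
            if c != subject_col and pd.api.types.is_numeric_dtype(answers[c])
        ]
    per_subject = answers.groupby(subject_col)[value_cols].mean()
    return pd.DataFrame(
        {
            "overall": per_subject.mean(axis=0),
            "sd": per_subject.std(axis=0, ddof=1),
            "n_subjects": per_subject.notna().sum(axis=0),
        }
    )


#: Reference table of simulated real-time answer-run decoding proportions
#: (seven subjects, 17 answer runs; columns = training-run windows counted
#: back from the answer run). Used to validate the two-stage aggregation
#: arithmetic against its published overall row.
_REFERENCE_ANSWER_TSV = """\
subject\trun\tt6\tt5_6\tt4_6\tt3_6\tt2_6\tt1_6\tanswer
S01\trun7\t1.00\t1.00\t1.00\t0.80\t0.60\t1.00\tyes
S02\trun7\t0.60\t0.80\t0.80\t0.80\t0.80\t0.80\tno
S02\trun8\t0.80\t0.80\t1.00\t1.00\t1.00\t1.00\tyes
S03\trun7\t0.40\t0.60\t0.60\t0.60\t0.60\t0.80\tyes
S03\trun8\t0.60\t0.60\t0.20\t0.40\t0.40\t0.20\tno
S05\trun7\t1.00\t1.00\t1.00\t1.00\t1.00\t1.00\tyes
S06\trun7\t0.40\t0.60\t0.60\t0.60\t0.80\t0.80\tyes
S06\trun8\t0.20\t0.80\t1.00\t0.80\t1.00\t1.00\tno
S08\trun7\t1.00\t1.00\t1.00\t1.00\t1.00\t1.00\tyes
S08\trun8\t0.40\t0.40\t0.40\t0.20\t0.40\t0.60\tno
S10\trun7\t0.80\t0.80\t0.60\t0.60\t0.60\t0.60\tyes
S10\trun8\t0.20\t0.80\t0.80\t1.00\t1.00\t1.00\tyes
S10\trun9\t1.00\t1.00\t1.00\t1.00\t1.00\t1.00\tno
S10\trun10\t0.00\t0.60\t0.80\t0.80\t1.00\t1.00\tyes
S10\trun11\t1.00\t0.60\t1.00\t1.00\t1.00\t1.00\tno
S10\trun12\t1.00\t0.80\t1.00\t1.00\t1.00\t1.00\tno
S10\trun13\t0.20\t0.60\t0.40\t0.60\t0.80\t1.00\tyes
"""

ANSWER_TABLE_COLUMNS = ["t6", "t5_6", "t4_6", "t3_6", "t2_6", "t1_6"]


def reference_answer_table() -> pd.DataFrame:
    """Published per-run answer-decoding proportions (see module docs)."""
    from io import StringIO

    return pd.read_csv(StringIO(_REFERENCE_ANSWER_TSV), sep="\t")
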