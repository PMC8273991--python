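"""Constrained Gaussian finite mixture model for septic-shock phenotyping.

The mixture assumes each of the 17 clinical features is Gaussian within class
with a variance *shared across classes* and all covariances fixed to zero
(one diagonal covariance matrix common to all components). Patient-days from
all ICU days are pooled into one sample; class transitions across days are
read off the per-day class assignments afterwards.

Model selection combines AIC, sample-size-adjusted BIC, normalized entropy, a
parametric bootstrap likelihood-ratio test of K vs K-1, a minimum class-size
rule (> 4% of patient-days) and a minimum class-membership-probability rule
(> 0.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "MixtureFit",
    "SelectionReport",
    "fit_fmm",
    "mixture_metrics",
    "bootstrap_lrt",
    "select_num_classes",
    "predict_classes",
    "characterize_classes",
    "transition_table",
]

_VAR_FLOOR_FACTOR = 1e-8  # times overall feature variance


@dataclass
class MixtureFit:
    """Fitted equal-variance diagonal Gaussian mixture.

    ``means`` is (K, d); ``shared_variances`` the length-d diagonal shared by
    all components; ``posteriors`` the (n, K) responsibility matrix on the
    training sample. ``loglik_path`` records the (non-decreasing) EM
    log-likelihood sequence of the winning restart.
    """

    K: int
    means: np.ndarray
    shared_variances: np.ndarray
    mixing_weights: np.ndarray
    loglik: float
    posteriors: np.ndarray
    converged: bool
    n_iter: int
    loglik_path: np.ndarray
    feature_names: list[str] | None = None

    @property
    def n_params(self) -> int:
        K, d = self.means.shape
        return K * d + d + (K - 1)

    def component_log_density(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of log [w_k N(x | mu_k, diag(v))]."""
        X = np.asarray(X, float)
        v = self.shared_variances
        const = -0.5 * (X.shape[1] * np.log(2.0 * np.pi) + np.log(v).sum())
        Mv = self.means / v
        cross = X @ Mv.T
        xq = (X * X / v).sum(axis=1)
        mq = (self.means * Mv).sum(axis=1)
        return const - 0.5 * (xq[:, None] - 2.0 * cross + mq[None, :]) \
            + np.log(self.mixing_weights)[None, :]

    def responsibilities(self, X: np.ndarray) -> tuple[np.ndarray, float]:
        """Posterior class probabilities for new rows and total log-likelihood."""
        lw = self.component_log_density(X)
        ll_rows = logsumexp(lw, axis=1)
        return np.exp(lw - ll_rows[:, None]), float(ll_rows.sum())

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(self.K, size=n, p=self.mixing_weights)
        sd = np.sqrt(self.shared_variances)
        return self.means[comp] + rng.standard_normal((n, self.means.shape[1])) * sd

    # -- persistence ---------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "model": "gaussian_mixture_shared_diagonal",
            "K": self.K,
            "feature_names": self.feature_names,
            "means": self.means.tolist(),
            "shared_variances": self.shared_variances.tolist(),
            "mixing_weights": self.mixing_weights.tolist(),
            "loglik": self.loglik,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str) -> "MixtureFit":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        return cls(K=doc["K"], means=np.array(doc["means"]),
                   shared_variances=np.array(doc["shared_variances"]),
                   mixing_weights=np.array(doc["mixing_weights"]),
                   loglik=doc["loglik"], posteriors=np.empty((0, doc["K"])),
                   converged=True, n_iter=0, loglik_path=np.array([doc["loglik"]]),
                   feature_names=doc.get("feature_names"))


class DegenerateFitError(RuntimeError):
    """All EM restarts collapsed (empty component or variance blow-up)."""


def _em_once(X, K, rng, tol, max_iter, var_floor):
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, n_clusters=K, random_state=int(rng.integers(2**31 - 1)))
    # harden k-means++ assignment into responsibilities
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2) if n * K * d < 5e7 \
        else (X * X).sum(1)[:, None] - 2 * X @ centers.T + (centers * centers).sum(1)[None, :]
    R = np.zeros((n, K))
    R[np.arange(n), np.argmin(d2, axis=1)] = 1.0

    sumsq = (X * X).sum(axis=0)
    loglik_path = []
    ll_prev = -np.inf
    fit = None
    for it in range(max_iter):
        # M-step
        Nk = R.sum(axis=0)
        if np.any(Nk < 1e-10):
            raise DegenerateFitError("empty component")
        w = Nk / n
        M = (R.T @ X) / Nk[:, None]
        v = np.maximum((sumsq - (Nk[:, None] * M * M).sum(axis=0)) / n, var_floor)
        fit = MixtureFit(K=K, means=M, shared_variances=v, mixing_weights=w,
                         loglik=np.nan, posteriors=R, converged=False, n_iter=it,
                         loglik_path=np.empty(0))
        # E-step
        R, ll = fit.responsibilities(X)
        loglik_path.append(ll)
        if ll + 1e-7 * max(1.0, abs(ll)) < ll_prev:
            raise RuntimeError(f"EM log-likelihood decreased: {ll_prev} -> {ll}")
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
            fit.converged = True
            fit.loglik = ll
            break
        ll_prev = ll
    fit.loglik = loglik_path[-1]
    fit.posteriors = R
    fit.n_iter = len(loglik_path)
    fit.loglik_path = np.asarray(loglik_path)
    return fit


def fit_fmm(matrix, K: int, n_starts: int = 20, tol: float = 1e-6,
            max_iter: int = 500, seed: int = 0) -> MixtureFit:
    """Fit the K-component equal-variance diagonal mixture by EM.

    Runs ``n_starts`` k-means++-initialized restarts and keeps the highest
    log-likelihood solution. Restarts that collapse (empty component) are
    redrawn; if every restart collapses a :class:`DegenerateFitError` is
    raised. ``tol`` is the relative log-likelihood change declaring
    convergence.
    """
    feature_names = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, float)
    n, d = X.shape
    if n <= K:
        raise ValueError(f"need more rows ({n}) than components ({K})")
    var_floor = _VAR_FLOOR_FACTOR * float(X.var(axis=0).mean())
    rng = np.random.default_rng(seed)
    best = None
    failures = 0
    starts_done = 0
    while starts_done < n_starts:
        try:
            fit = _em_once(X, K, rng, tol, max_iter, var_floor)
        except DegenerateFitError:
            failures += 1
            if failures >= 3 * n_starts:
                raise DegenerateFitError(
                    f"all restarts degenerate for K={K} (n={n})")
            continue
        starts_done += 1
        if best is None or fit.loglik > best.loglik:
            best = fit
    best.feature_names = feature_names
    return best


def mixture_metrics(fit: MixtureFit) -> tuple[float, float, float]:
    """Return (AIC, SABIC, normalized entropy) for a fitted mixture.

    AIC = -2 loglik + 2 p; SABIC = -2 loglik + p log((n+2)/24) with the
    sample-size-adjusted penalty; entropy is the normalized form
    ``1 - sum_i sum_k (-p_ik ln p_ik) / (n ln K)`` in [0, 1], with 1 meaning
    perfectly crisp assignment (returned as 1 for K=1 by convention).
    """
    n = fit.posteriors.shape[0]
    p = fit.n_params
    aic = -2.0 * fit.loglik + 2.0 * p
    sabic = -2.0 * fit.loglik + p * np.log((n + 2.0) / 24.0)
    if fit.K == 1:
        entropy = 1.0
    else:
        post = np.clip(fit.posteriors, 1e-300, 1.0)
        ent = -(post * np.log(post)).sum()
        entropy = 1.0 - ent / (n * np.log(fit.K))
    return float(aic), float(sabic), float(entropy)


def bootstrap_lrt(matrix, K: int, B: int = 100, seed: int = 0,
                  n_starts: int = 2, tol: float = 1e-6, max_iter: int = 300,
                  ) -> dict:
    """Parametric bootstrap likelihood-ratio test of K components vs K-1.

    The observed statistic is ``2 (loglik_K - loglik_{K-1})``; ``B`` bootstrap
    samples of the original size are drawn from the fitted (K-1)-component
    model and both models refit on each (same EM settings as the observed
    fits). The p-value uses the add-one convention
    ``(1 + #{LR_b >= LR_obs}) / (B + 1)`` and therefore lies in (0, 1].
    """
    if K < 2:
        raise ValueError("BLRT needs K >= 2")
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(matrix, float)
    n = X.shape[0]
    fit0 = fit_fmm(X, K - 1, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed)
    fit1 = fit_fmm(X, K, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed + 1)
    lr_obs = 2.0 * (fit1.loglik - fit0.loglik)
    rng = np.random.default_rng([seed, K, 0x1b])
    lr_boot = np.empty(B)
    for b in range(B):
        Xb = fit0.sample(n, rng)
        sub = int(rng.integers(2**31 - 1))
        f0 = fit_fmm(Xb, K - 1, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=sub)
        f1 = fit_fmm(Xb, K, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=sub + 1)
        lr_boot[b] = 2.0 * (f1.loglik - f0.loglik)
    p = (1.0 + float((lr_boot >= lr_obs).sum())) / (B + 1.0)
    return {"lr_obs": float(lr_obs), "lr_boot": lr_boot, "p_value": float(p)}


def membership_stability(fit: MixtureFit, per_row: bool = False) -> float:
    """Minimum class-membership probability of a fit.

    Default: the minimum over classes of the *mean* max-posterior probability
    among rows assigned (argmax) to that class. With ``per_row`` the stricter
    minimum over rows of the max posterior is returned instead.
    """
    maxpost = fit.posteriors.max(axis=1)
    if per_row:
        return float(maxpost.min())
    labels = fit.posteriors.argmax(axis=1)
    return float(min(maxpost[labels == k].mean() if (labels == k).any() else 0.0
                     for k in range(fit.K)))


@dataclass
class SelectionReport:
    """Per-K selection statistics and the chosen class count."""

    table: pd.DataFrame
    chosen_K: int | None
    reasons: dict[int, str]
    fits: dict[int, MixtureFit] = field(default_factory=dict)


def select_num_classes(matrix, K_range=range(2, 9), B: int = 100, seed: int = 0,
                       n_starts: int = 20, tol: float = 1e-6, max_iter: int = 500,
                       min_class_frac: float = 0.04, min_membership: float = 0.8,
                       blrt_alpha: float = 0.05, aic_flatness: float = 0.01,
                       per_row_membership: bool = False) -> SelectionReport:
    """Composite class-number selection over candidate component counts.

    Each candidate K is fit; a K is disqualified if its smallest assigned
    class holds <= ``min_class_frac`` of patient-days, if its minimum
    membership probability is <= ``min_membership``, or if the bootstrap LRT
    of K vs K-1 is non-significant at ``blrt_alpha``. Among the qualifiers the
    chosen K is the largest whose AIC improvement over K-1 exceeds
    ``aic_flatness`` of the AIC range across candidates (where the
    improvement flattens, stop); if every qualifier is flat the smallest
    qualifier is chosen on parsimony grounds, and exact improvement ties are
    broken by higher entropy. The full per-K table is returned so any other
    rule can be audited.
    """
    X = np.asarray(matrix, float)
    n = X.shape[0]
    ks = sorted(K_range)
    fit_ks = sorted({max(k - 1, 1) for k in ks} | set(ks))
    fits: dict[int, MixtureFit] = {}
    rows = []
    stats: dict[int, dict] = {}
    for k in fit_ks:
        fit = fit_fmm(matrix, k, n_starts=n_starts, tol=tol, max_iter=max_iter,
                      seed=seed + 1000 * k)
        fits[k] = fit
        aic, sabic, ent = mixture_metrics(fit)
        labels = fit.posteriors.argmax(axis=1)
        frac = np.bincount(labels, minlength=k) / n
        stats[k] = {"aic": aic, "sabic": sabic, "entropy": ent,
                    "min_frac": float(frac.min()),
                    "min_membership": membership_stability(fit, per_row=per_row_membership)}

    reasons: dict[int, str] = {}
    for k in ks:
        st = stats[k]
        blrt = bootstrap_lrt(X, k, B=B, seed=seed + 17 * k, tol=tol)
        st["blrt_p"] = blrt["p_value"]
        st["aic_improvement"] = stats[k - 1]["aic"] - st["aic"] if k - 1 in stats else np.nan
        why = []
        if st["min_frac"] <= min_class_frac:
            why.append(f"smallest class fraction {st['min_frac']:.3f} <= {min_class_frac}")
        if st["min_membership"] <= min_membership:
            why.append(f"min membership {st['min_membership']:.3f} <= {min_membership}")
        if st["blrt_p"] >= blrt_alpha:
            why.append(f"BLRT p {st['blrt_p']:.3f} >= {blrt_alpha}")
        st["qualified"] = not why
        reasons[k] = "; ".join(why) if why else "qualified"
        rows.append({"K": k, **{c: st[c] for c in (
            "aic", "sabic", "entropy", "blrt_p", "min_frac", "min_membership",
            "aic_improvement", "qualified")}})
    table = pd.DataFrame(rows)

    qualified = [k for k in ks if stats[k]["qualified"]]
    chosen = None
    if qualified:
        aics = table.set_index("K")["aic"]
        aic_range = float(aics.max() - aics.min()) or 1.0
        improving = [k for k in qualified
                     if stats[k]["aic_improvement"] > aic_flatness * aic_range]
        if improving:
            # candidate counts are unique, so "largest" cannot tie; an exact
            # AIC tie between candidates would fall to the higher entropy
            chosen = max(improving, key=lambda k: (k, stats[k]["entropy"]))
        else:
            chosen = min(qualified)
            reasons[chosen] += " (chosen on parsimony: AIC improvement flat)"
    return SelectionReport(table=table, chosen_K=chosen, reasons=reasons, fits=fits)


def predict_classes(fit: MixtureFit, matrix) -> tuple[np.ndarray, np.ndarray]:
    """Assign new patient-days under a frozen fit.

    Returns ``(labels, posteriors)`` with 1-based labels; label = argmax
    posterior, ties broken toward the lowest class index. The new matrix must
    carry the same columns (same units) as the training matrix.
    """
    if isinstance(matrix, pd.DataFrame) and fit.feature_names is not None:
        if list(matrix.columns) != list(fit.feature_names):
            raise KeyError(
                f"column mismatch: model expects {fit.feature_names}, got {list(matrix.columns)}")
    X = np.asarray(matrix, float)
    post, _ = fit.responsibilities(X)
    return post.argmax(axis=1) + 1, post


_NAME_RULES = ("critical", "renal dysfunction", "respiratory failure", "mild")


def characterize_classes(fit: MixtureFit) -> dict[int, str]:
    """Attach clinical names to fitted classes by rule priority.

    Highest lactate mean -> "critical"; then highest creatinine -> "renal
    dysfunction"; then highest PaCO2 -> "respiratory failure"; then lowest
    age -> "mild"; the remaining (largest) class -> "baseline". Each name is
    used at most once; with K=1 the single class is "baseline"; classes beyond
    the five rules are "unnamed".
    """
    if fit.feature_names is None:
        raise ValueError("fit has no feature names; fit on a DataFrame")
    names = {}
    if fit.K == 1:
        return {1: "baseline"}
    cols = {f: fit.feature_names.index(f)
            for f in ("lactate_max", "creatinine", "paco2_max", "age")}
    remaining = list(range(fit.K))
    for rule, feat, take_max in (("critical", "lactate_max", True),
                                 ("renal dysfunction", "creatinine", True),
                                 ("respiratory failure", "paco2_max", True),
                                 ("mild", "age", False)):
        if len(remaining) <= 1:
            break
        vals = fit.means[remaining, cols[feat]]
        pick = remaining[int(np.argmax(vals) if take_max else np.argmin(vals))]
        names[pick + 1] = rule
        remaining.remove(pick)
    if remaining:
        largest = max(remaining, key=lambda k: fit.mixing_weights[k])
        names[largest + 1] = "baseline"
        remaining.remove(largest)
    for k in remaining:
        names[k + 1] = "unnamed"
    return dict(sorted(names.items()))


def transition_table(labels: pd.DataFrame, K: int | None = None,
                     ) -> dict[tuple[int, int], pd.DataFrame]:
    """Class-transition counts between consecutive observed days.

    ``labels`` has columns ``patient_id, day, label`` (1-based labels). For
    each consecutive day pair (0,1), (1,2), (2,3), (3,7) the K x K count
    matrix of i -> j moves is returned; a patient contributes to a pair only
    if observed on both days.
    """
    if labels.duplicated(["patient_id", "day"]).any():
        raise ValueError("duplicate patient-day rows")
    K = K or int(labels["label"].max())
    days = sorted(labels["day"].unique())
    wide = labels.pivot(index="patient_id", columns="day", values="label")
    out = {}
    for d0, d1 in zip(days[:-1], days[1:]):
        sub = wide[[d0, d1]].dropna().astype(int)
        counts = np.zeros((K, K), dtype=int)
        for (i, j), c in sub.value_counts().items():
            counts[i - 1, j - 1] = c
        idx = pd.RangeIndex(1, K + 1)
        out[(d0, d1)] = pd.DataFrame(counts, index=idx.rename("from"),
                                     columns=idx.rename("to"))
    return out
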