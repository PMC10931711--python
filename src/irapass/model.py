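"""The IRAPAss construction: from PDUI/expression tables to a linear
immunotherapy-response score.

Stages, in pipeline order:

1. **Correlation score (CS).** Within one sample group, for every
   (gene x, APA event y) pair, Pearson correlation ``Cor_xy`` with p-value
   ``P_xy`` gives ``CS_xy = -log10(P_xy + 1e-20) * sign(Cor_xy)`` — a
   signed evidence score bounded by 20 in magnitude.
2. **Preranked GSEA.** For each event, genes ranked by CS are tested
   against pathway gene sets with a weighted Kolmogorov-Smirnov running
   sum; significance by gene-label permutation.
3. **pathAPAscore.** ``1 - 2p`` when ES > 0, ``2p - 1`` when ES < 0; the
   event-pathway association statistic, screened at > 0.995 with
   FDR < 0.05.
4. **Cross-group / cross-cohort screen.** Pairs must flip NES sign between
   responders and non-responders and replicate with the same orientation
   in both discovery cohorts.
5. **Survival selection.** Univariate Cox (p < 0.05) then LASSO Cox with
   cross-validated penalty (1-SE rule) on standardized PDUI features.
6. **Scorer.** A linear model over raw PDUI features (the published
   10-term instance ships with the package); an optional one-hidden-layer
   MLP architecture exports its equivalent linear form.
7. **Evaluation.** ROC/AUC against response, Youden-optimal cutoff,
   Kaplan-Meier with log-rank, and multivariate Cox for independence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from irapass.io import (
    ClinicalTable,
    EventId,
    ExpressionTable,
    GeneSetCollection,
    PduiTable,
    ValidationError,
)
from irapass.diff_apa import bh_fdr

__all__ = [
    "CsProfile",
    "IrapassModel",
    "ScoreEvaluation",
    "published_model",
    "PUBLISHED_COEFFICIENTS",
    "correlation_score",
    "preranked_gsea",
    "path_apa_score",
    "event_pathway_associations",
    "screen_immune_events",
    "univariate_cox",
    "lasso_cox",
    "fit_scorer",
    "evaluate",
    "build_scoring_system",
]

logger = logging.getLogger("irapass")

CS_PSEUDOCOUNT = 1e-20
PATH_APA_THRESHOLD = 0.995
FDR_THRESHOLD = 0.05

#: The published 10-term linear scoring formula (intercept 0): the score of
#: a sample is the dot product of these coefficients with its raw PDUI
#: values at the named events.
PUBLISHED_COEFFICIENTS: tuple[tuple[str, float], ...] = (
    ("AIM2|chr1|159062567", 0.785057366),
    ("BAX|chr19|48960961", 0.660980225),
    ("COL27A1|chr9|114310700", -0.564149737),
    ("CTTN|chr11|70422660", -0.060074512),
    ("ERH|chr14|69380489", -0.037628233),
    ("GTF3C2-AS1|chr2|27337588", -1.267010808),
    ("NASP|chr1|45618212", 0.819018066),
    ("RPL13|chr16|89563035", 0.974817872),
    ("TAF15|chr17|35847057", -0.624692976),
    ("TMEM63A|chr1|225841036", -0.279070169),
)


# ---------------------------------------------------------------------------
# Correlation score
# ---------------------------------------------------------------------------


@dataclass
class CsProfile:
    """CS / Cor / P matrices (genes x events) for one sample group."""

    cs: pd.DataFrame
    cor: pd.DataFrame
    p: pd.DataFrame
    n_samples: int


def correlation_score(expr: ExpressionTable, pdui: PduiTable,
                      samples: list[str], min_pairs: int = 5) -> CsProfile:
    """CS_xy = -log10(P_xy + 1e-20) * sign(Cor_xy) over a sample subset.

    Pearson r and its two-sided p per (gene, event) pair on
    pairwise-complete observations; pairs with fewer than ``min_pairs``
    complete observations, or a constant vector, yield missing CS.
    """
    samples = [s for s in samples if s in expr.data.columns and s in pdui.data.columns]
    if len(samples) < min_pairs:
        raise ValidationError(f"need >= {min_pairs} samples, got {len(samples)}")
    g_mat = expr.data[samples].to_numpy()
    genes = list(expr.data.index)
    events = list(pdui.data.index)
    n_g = len(genes)
    cor = np.full((n_g, len(events)), np.nan)
    pval = np.full((n_g, len(events)), np.nan)
    for j, ev in enumerate(events):
        a = pdui.data.loc[ev, samples].to_numpy(float)
        ok = ~np.isnan(a)
        n = int(ok.sum())
        if n < min_pairs:
            continue
        av = a[ok] - a[ok].mean()
        gv = g_mat[:, ok] - g_mat[:, ok].mean(axis=1, keepdims=True)
        denom = np.sqrt((gv**2).sum(axis=1) * (av**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((gv @ av) / denom, -1.0, 1.0)
        r[denom == 0] = np.nan  # constant gene or constant event
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        pv = 2 * stats.t.sf(np.abs(t), df=n - 2)
        cor[:, j] = r
        pval[:, j] = pv
    cs = -np.log10(pval + CS_PSEUDOCOUNT) * np.sign(cor)
    return CsProfile(
        cs=pd.DataFrame(cs, index=genes, columns=events),
        cor=pd.DataFrame(cor, index=genes, columns=events),
        p=pd.DataFrame(pval, index=genes, columns=events),
        n_samples=len(samples),
    )


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _running_es(weights: np.ndarray, hit_pos: np.ndarray, n_total: int) -> float:
    """Enrichment score: extreme of the weighted KS running sum.

    ``weights`` are |CS|^w in ranked order; ``hit_pos`` are the (sorted)
    0-based positions of the set members.  Hits step up by their weight
    share; misses step down by 1/(N - Nh).  Returns the deviation of
    largest magnitude (positive maximum or negative minimum).
    """
    nh = len(hit_pos)
    if nh == 0 or nh == n_total:
        # degenerate: no misses (or no hits) — the walk returns to zero;
        # report the maximum deviation of that degenerate walk
        if nh == 0:
            return 0.0
        w = weights[hit_pos]
        tot = w.sum()
        if tot <= 0:
            return 0.0
        run = np.cumsum(w / tot)
        return float(run.max())
    w = weights[hit_pos]
    tot = w.sum()
    if tot <= 0:
        w = np.ones(nh)
        tot = float(nh)
    miss = 1.0 / (n_total - nh)
    gain = np.cumsum(w / tot)
    # running sum just after hit i: gains so far minus misses so far
    after_hit = gain - (hit_pos + 1 - np.arange(1, nh + 1)) * miss
    # running sum just before hit i (all misses up to that rank)
    before_hit = gain - w / tot - (hit_pos - np.arange(nh)) * miss
    hi = after_hit.max()
    lo = before_hit.min()
    return float(hi if hi >= -lo else lo)


def _null_es(weights: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Null ES distribution for random hit positions (vectorized)."""
    n_total = len(weights)
    k = set_size
    if k >= n_total:
        return np.array([_running_es(weights, np.arange(n_total), n_total)
                         for _ in range(n_perm)])
    pos = np.argpartition(rng.random((n_perm, n_total)), k, axis=1)[:, :k]
    pos.sort(axis=1)
    w = weights[pos]
    wsum = w.sum(axis=1, keepdims=True)
    uniform = wsum[:, 0] <= 0
    if np.any(uniform):
        w[uniform] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    miss = 1.0 / (n_total - k)
    gain = np.cumsum(w / wsum, axis=1)
    idx = np.arange(k)
    after = gain - (pos + 1 - (idx + 1)) * miss
    before = gain - w / wsum - (pos - idx) * miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def preranked_gsea(ranked_cs: pd.Series, gene_sets: GeneSetCollection,
                   weight: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_size: int = 5) -> pd.DataFrame:
    """Weighted preranked GSEA of every pathway against one CS ranking.

    ``ranked_cs`` maps gene -> CS (no missing values); genes are ranked by
    CS descending.  The null is gene-label permutation (random set
    positions).  NES normalizes ES by the mean |null ES| of matching sign;
    perm_p is two-sided with the add-one estimator; fdr_q is BH across
    pathways.  Sets smaller than ``min_size`` after intersection with the
    universe are dropped.
    """
    if ranked_cs.isna().any():
        raise ValidationError("ranked CS must have no missing values")
    if len(ranked_cs) == 0:
        raise ValidationError("empty ranked universe")
    order = ranked_cs.sort_values(ascending=False, kind="mergesort")
    universe = list(order.index)
    pos_of = {g: i for i, g in enumerate(universe)}
    weights = np.abs(order.to_numpy()) ** weight
    n_total = len(universe)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(gene_sets.sets):
        members = sorted(set(gene_sets.sets[name]) & set(universe))
        if len(members) < min_size:
            continue
        if len(members) == n_total:
            logger.warning("preranked_gsea: set %s equals the whole universe", name)
        hit_pos = np.sort(np.array([pos_of[g] for g in members]))
        es = _running_es(weights, hit_pos, n_total)
        k = len(members)
        if k not in null_cache:
            null_cache[k] = _null_es(weights, k, n_perm, rng)
        null = null_cache[k]
        p = (1 + np.sum(np.abs(null) >= abs(es) - 1e-12)) / (n_perm + 1)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append((name, k, es, nes, p))
    out = pd.DataFrame(rows, columns=["pathway", "size", "es", "nes", "perm_p"])
    out["fdr_q"] = bh_fdr(out["perm_p"]).to_numpy() if len(out) else []
    out["path_apa_score"] = path_apa_score(out["es"].to_numpy(), out["perm_p"].to_numpy())
    return out.set_index("pathway")


def path_apa_score(es, p):
    """1 - 2p when ES > 0; 2p - 1 when ES < 0; 0 at ES = 0 (by continuity)."""
    es = np.asarray(es, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.where(es > 0, 1.0 - 2.0 * p, np.where(es < 0, 2.0 * p - 1.0, 0.0))
    if out.ndim == 0:
        return float(out)
    return out


def event_pathway_associations(expr: ExpressionTable, pdui: PduiTable,
                               clinical: ClinicalTable,
                               gene_sets: GeneSetCollection,
                               n_perm: int = 1000, seed: int = 0,
                               min_size: int = 5,
                               events: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Per-group (responders / non-responders) event-pathway association.

    For each group: a CS profile over the group's samples, then preranked
    GSEA of the CS ranking of every event.  Returns long tables indexed by
    (event_id, pathway) keyed ``"responders"`` / ``"nonresponders"``.
    """
    resp = clinical.response_mask()
    out = {}
    for key, want in (("responders", True), ("nonresponders", False)):
        samples = [s for s in resp.index[resp == want] if s in pdui.data.columns]
        profile = correlation_score(expr, pdui, samples)
        tables = []
        event_list = events if events is not None else list(profile.cs.columns)
        for j, ev in enumerate(event_list):
            cs = profile.cs[ev].dropna()
            if len(cs) < min_size:
                continue
            res = preranked_gsea(cs, gene_sets, n_perm=n_perm,
                                 seed=seed + 7919 * j + (want * 104729),
                                 min_size=min_size)
            res = res.reset_index()
            res.insert(0, "event_id", ev)
            tables.append(res)
        out[key] = (pd.concat(tables, ignore_index=True) if tables
                    else pd.DataFrame(columns=["event_id", "pathway", "size", "es",
                                               "nes", "perm_p", "fdr_q",
                                               "path_apa_score"]))
    return out


def screen_immune_events(associations: dict[str, dict[str, pd.DataFrame]],
                         score_threshold: float = PATH_APA_THRESHOLD,
                         fdr_threshold: float = FDR_THRESHOLD) -> tuple[pd.DataFrame, list[str]]:
    """Three sequential filters to the candidate immune-related event set.

    ``associations`` maps cohort name -> {"responders": df, "nonresponders":
    df} as produced by :func:`event_pathway_associations`.  Filters, in
    order: (1) |pathAPAscore| > threshold and FDR < threshold in at least
    one group; (2) opposite NES sign between the groups; (3) the pair
    survives (1)+(2) in *both* cohorts with the same orientation (sign of
    the responder NES).  Returns the surviving pairs and the distinct event
    list.
    """
    if len(associations) < 2:
        raise ValidationError("screening needs association tables for two cohorts")
    per_cohort = {}
    for cohort, groups in associations.items():
        for key in ("responders", "nonresponders"):
            if key not in groups:
                raise ValidationError(f"cohort {cohort}: missing {key} associations")
        r = groups["responders"].set_index(["event_id", "pathway"])
        nr = groups["nonresponders"].set_index(["event_id", "pathway"])
        joint = r.join(nr, how="inner", lsuffix="_r", rsuffix="_n")
        sig = (
            ((joint["path_apa_score_r"].abs() > score_threshold)
             & (joint["fdr_q_r"] < fdr_threshold))
            | ((joint["path_apa_score_n"].abs() > score_threshold)
               & (joint["fdr_q_n"] < fdr_threshold))
        )
        opposite = np.sign(joint["nes_r"]) == -np.sign(joint["nes_n"])
        opposite &= joint["nes_r"] != 0
        kept = joint[sig & opposite].copy()
        kept["orientation"] = np.sign(kept["nes_r"]).astype(int)
        per_cohort[cohort] = kept
    cohorts = list(per_cohort)
    merged = per_cohort[cohorts[0]][["orientation"]].join(
        per_cohort[cohorts[1]][["orientation"]], how="inner",
        lsuffix="_c1", rsuffix="_c2",
    )
    merged = merged[merged["orientation_c1"] == merged["orientation_c2"]]
    pairs = merged.reset_index().rename(columns={"orientation_c1": "orientation"})
    pairs = pairs.drop(columns=["orientation_c2"])
    events = sorted(pairs["event_id"].unique())
    logger.info("screen_immune_events: %d pairs, %d distinct events", len(pairs), len(events))
    return pairs, events


# ---------------------------------------------------------------------------
# Survival feature selection
# ---------------------------------------------------------------------------


def _feature_frame(pdui: PduiTable, events: list[str], samples: list[str],
                   impute: bool = True) -> pd.DataFrame:
    """Samples x events PDUI feature matrix (mean-imputed when requested)."""
    x = pdui.data.loc[events, samples].T.astype(float)
    if impute:
        x = x.fillna(x.mean())
    return x


def univariate_cox(features: pd.DataFrame, os_time: pd.Series, os_event: pd.Series,
                   p_threshold: float = 0.05) -> pd.DataFrame:
    """Single-feature proportional-hazards fits on standardized features.

    Returns a table (hr, p, passed) per feature; constant or non-converging
    features are skipped with a warning.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    n_deaths = int(os_event.sum())
    if n_deaths < 10:
        raise ValidationError(f"need >= 10 observed events, got {n_deaths}")
    rows = []
    for feat in features.columns:
        x = features[feat].astype(float)
        sd = x.std()
        if not np.isfinite(sd) or sd == 0:
            logger.warning("univariate_cox: %s is constant, skipped", feat)
            continue
        df = pd.DataFrame({
            "x": (x - x.mean()) / sd,
            "time": os_time.reindex(features.index).astype(float),
            "event": os_event.reindex(features.index).astype(int),
        }).dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            logger.warning("univariate_cox: %s did not converge (%s), skipped", feat, exc)
            continue
        hr = float(np.exp(cph.params_["x"]))
        p = float(cph.summary.loc["x", "p"])
        rows.append((feat, hr, p, p < p_threshold))
    return pd.DataFrame(rows, columns=["feature", "hr", "p", "passed"]).set_index("feature")


def _breslow_pll(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood of linear predictors ``eta``."""
    order = np.argsort(-time, kind="mergesort")
    eta, time, event = eta[order], time[order], event[order]
    log_risk = np.logaddexp.accumulate(eta)
    # ties: the risk set of a death at time t contains everyone with
    # time >= t, i.e. the cumulative sum at the last index of the tie group
    last = np.arange(len(time))
    for i in range(len(time) - 2, -1, -1):
        if time[i] == time[i + 1]:
            last[i] = last[i + 1]
    return float(np.sum(event * (eta - log_risk[last])))


def lasso_cox(features: pd.DataFrame, os_time: pd.Series, os_event: pd.Series,
              cv_folds: int = 5, seed: int = 0, n_alphas: int = 50) -> pd.DataFrame:
    """L1-penalized Cox over a log-spaced penalty path, CV + 1-SE rule.

    Features are standardized; the penalty is chosen by k-fold
    cross-validated Breslow partial likelihood at the 1-SE rule (falling
    back to the CV optimum if the 1-SE penalty zeroes everything).
    Returns the nonzero coefficients at the chosen penalty.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if features.shape[1] < 2:
        raise ValidationError("LASSO needs >= 2 features passing the univariate screen")
    x = features.astype(float)
    x = (x - x.mean()) / x.std().replace(0, 1.0)
    x = x.fillna(0.0)
    time = os_time.reindex(x.index).to_numpy(float)
    event = os_event.reindex(x.index).to_numpy(bool)
    y = Surv.from_arrays(event=event, time=time)

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(x.to_numpy(), y)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(x))
    folds = np.array_split(idx, cv_folds)
    pll = np.full((cv_folds, len(alphas)), np.nan)
    for k, test in enumerate(folds):
        train = np.setdiff1d(idx, test)
        if event[train].sum() < 2 or event[test].sum() < 1:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                   fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                m.fit(x.to_numpy()[train], y[train])
            except (ValueError, ArithmeticError):
                continue
        fitted = np.asarray(m.alphas_)
        for j, alpha in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted - alpha)))
            eta = x.to_numpy()[test] @ m.coef_[:, jj]
            pll[k, j] = _breslow_pll(eta, time[test], event[test])
    mean_pll = np.nanmean(pll, axis=0)
    if np.all(np.isnan(mean_pll)):
        raise ValidationError("cross-validation failed on every fold")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se_pll = np.nanstd(pll, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(pll), axis=0))
    best = int(np.nanargmax(mean_pll))
    threshold = mean_pll[best] - (se_pll[best] if np.isfinite(se_pll[best]) else 0.0)
    # largest penalty (alphas are descending) within 1 SE of the optimum
    candidates = [j for j in range(best + 1) if mean_pll[j] >= threshold]
    chosen = candidates[0] if candidates else best
    coefs = pd.Series(path.coef_[:, chosen], index=x.columns)
    if (coefs == 0).all():
        logger.warning("lasso_cox: 1-SE penalty zeroed all coefficients; "
                       "falling back to the CV-optimal penalty")
        coefs = pd.Series(path.coef_[:, best], index=x.columns)
    selected = coefs[coefs != 0]
    out = pd.DataFrame({"coef": selected})
    out.attrs["alpha"] = float(alphas[chosen])
    out.attrs["cv_mean_pll"] = mean_pll
    return out


# ---------------------------------------------------------------------------
# The scorer
# ---------------------------------------------------------------------------


@dataclass
class IrapassModel:
    """Linear immune-response APA scorer: score = coef . PDUI + intercept."""

    features: list[str]
    coefficients: np.ndarray
    intercept: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(set(self.features)) != len(self.features):
            raise ValidationError("model features must be unique")
        if len(self.features) != len(self.coefficients):
            raise ValidationError("features and coefficients length mismatch")

    @property
    def n_features(self) -> int:
        return len(self.features)

    def score(self, pdui, impute_missing: bool = False) -> pd.Series:
        """IRAPAss score per sample.

        ``pdui`` may be a :class:`PduiTable`, an events x samples frame, or
        a mapping feature -> value for a single sample.  Missing features
        raise unless ``impute_missing`` (per-feature mean over the provided
        samples; NaN entries likewise).
        """
        if isinstance(pdui, PduiTable):
            frame = pdui.data
        elif isinstance(pdui, pd.DataFrame):
            frame = pdui
        else:
            frame = pd.DataFrame({"sample": pd.Series(dict(pdui), dtype=float)})
        missing = [f for f in self.features if f not in frame.index]
        if missing:
            if not impute_missing:
                raise ValidationError(f"missing model features: {missing}")
            frame = pd.concat([frame, pd.DataFrame(np.nan, index=missing,
                                                   columns=frame.columns)])
        x = frame.loc[self.features].astype(float)
        if x.isna().any().any():
            if not impute_missing:
                bad = x.index[x.isna().any(axis=1)].tolist()
                raise ValidationError(f"NaN PDUI for model features: {bad}")
            row_means = x.mean(axis=1).fillna(0.0)
            x = x.apply(lambda col: col.fillna(row_means))
        scores = self.coefficients @ x.to_numpy() + self.intercept
        return pd.Series(scores, index=frame.columns, name="irapass")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coefficient": self.coefficients},
                            index=pd.Index(self.features, name="event_id"))


def published_model() -> IrapassModel:
    """The shipped 10-term published scoring formula (intercept 0)."""
    feats = [f for f, _ in PUBLISHED_COEFFICIENTS]
    coefs = [c for _, c in PUBLISHED_COEFFICIENTS]
    return IrapassModel(features=feats, coefficients=np.array(coefs),
                        intercept=0.0, metadata={"source": "published"})


def _sigmoid(z):
    return 0.5 * (1 + np.tanh(z / 2))


class _TinyMlp:
    """One-hidden-layer network with identity-initialized hidden weights.

    The hidden layer starts at W1 = I, b1 = 0 with ReLU activation; because
    PDUI inputs are non-negative, pre-activations typically stay positive
    and the trained network admits an exact equivalent-linear export
    (checked at export time).
    """

    def __init__(self, n_features: int, seed: int = 0, lr: float = 0.5,
                 n_iter: int = 2000):
        rng = np.random.default_rng(seed)
        self.w1 = np.eye(n_features) + 0.01 * rng.normal(size=(n_features, n_features))
        self.b1 = np.zeros(n_features)
        self.w2 = 0.01 * rng.normal(size=n_features)
        self.b2 = 0.0
        self.lr = lr
        self.n_iter = n_iter

    def _forward(self, x):
        h_pre = x @ self.w1 + self.b1
        h = np.maximum(h_pre, 0.0)
        return h_pre, h, h @ self.w2 + self.b2

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_TinyMlp":
        n = len(x)
        for _ in range(self.n_iter):
            h_pre, h, z = self._forward(x)
            err = _sigmoid(z) - y
            g_w2 = h.T @ err / n
            g_b2 = err.mean()
            dh = np.outer(err, self.w2) * (h_pre > 0)
            g_w1 = x.T @ dh / n
            g_b1 = dh.mean(axis=0)
            self.w2 -= self.lr * g_w2
            self.b2 -= self.lr * g_b2
            self.w1 -= self.lr * g_w1
            self.b1 -= self.lr * g_b1
        return self

    def equivalent_linear(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        h_pre = x @ self.w1 + self.b1
        if np.any(h_pre < 0):
            logger.warning("mlp export: %.1f%% of hidden pre-activations negative; "
                           "linear export is approximate",
                           100 * np.mean(h_pre < 0))
        return self.w1 @ self.w2, float(self.b1 @ self.w2 + self.b2)


def fit_scorer(features: pd.DataFrame, response: pd.Series,
               architecture: str = "linear", split: float = 0.7,
               seed: int = 0) -> tuple[IrapassModel, dict]:
    """Train the scorer on a random 70/30 split of the pooled cohort.

    ``features`` is samples x events (raw PDUI); ``response`` is boolean
    (True = responder).  The canonical architecture is a single linear
    layer trained by logistic loss — the published formula is linear — and
    ``mlp`` adds one identity-initialized hidden layer whose equivalent
    linear form is exported into the returned model.  Returns the model
    and a dict with train/test indices.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    common = [s for s in features.index if s in response.index]
    if len(common) < 10:
        raise ValidationError(f"need >= 10 training samples, got {len(common)}")
    x_all = features.loc[common].astype(float)
    x_all = x_all.fillna(x_all.mean())
    y_all = response.loc[common].astype(int)
    train_idx, test_idx = train_test_split(
        np.arange(len(common)), train_size=split, random_state=seed,
        stratify=y_all.to_numpy(),
    )
    x_tr = x_all.iloc[train_idx].to_numpy()
    y_tr = y_all.iloc[train_idx].to_numpy()
    if architecture == "linear":
        clf = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized
        clf.fit(x_tr, y_tr)
        coefs, intercept = clf.coef_[0], float(clf.intercept_[0])
    elif architecture == "mlp":
        net = _TinyMlp(x_tr.shape[1], seed=seed).fit(x_tr, y_tr.astype(float))
        coefs, intercept = net.equivalent_linear(x_tr)
    else:
        raise ValidationError(f"unknown architecture {architecture!r}")
    model = IrapassModel(
        features=list(features.columns),
        coefficients=coefs,
        intercept=intercept,
        metadata={"architecture": architecture, "split": split, "seed": seed},
    )
    split_info = {
        "train_samples": [common[i] for i in train_idx],
        "test_samples": [common[i] for i in test_idx],
    }
    return model, split_info


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ScoreEvaluation:
    scores: pd.Series
    auc: float | None
    roc: pd.DataFrame | None
    cutoff: float | None
    groups: pd.Series | None              # "high" / "low"
    logrank_p: float | None
    km_curves: dict[str, pd.DataFrame] | None
    cox_summary: pd.DataFrame | None


def evaluate(scores: pd.Series, response: pd.Series | None = None,
             os_time: pd.Series | None = None, os_event: pd.Series | None = None,
             covariates: pd.DataFrame | None = None,
             min_events: int = 10) -> ScoreEvaluation:
    """ROC/AUC vs response, Youden cutoff, Kaplan-Meier and multivariate Cox."""
    from sklearn.metrics import roc_curve, roc_auc_score

    auc = roc = cutoff = groups = logrank_p = km_curves = cox_summary = None

    if response is not None:
        y = response.reindex(scores.index).dropna().astype(int)
        s = scores.loc[y.index]
        if y.nunique() < 2:
            logger.warning("evaluate: single response class, ROC skipped")
        else:
            auc = float(roc_auc_score(y, s))
            fpr, tpr, thr = roc_curve(y, s)
            roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
            youden = tpr - fpr
            cutoff = float(thr[int(np.argmax(youden))])
            groups = pd.Series(np.where(scores >= cutoff, "high", "low"),
                               index=scores.index, name="irapass_group")

    if os_time is not None and os_event is not None and groups is not None:
        from lifelines import CoxPHFitter, KaplanMeierFitter
        from lifelines.statistics import logrank_test

        surv = pd.DataFrame({
            "time": os_time.reindex(scores.index).astype(float),
            "event": os_event.reindex(scores.index).astype(int),
            "high": (groups == "high").astype(int),
        }).dropna()
        if int(surv["event"].sum()) >= min_events and surv["high"].nunique() == 2:
            hi = surv[surv["high"] == 1]
            lo = surv[surv["high"] == 0]
            lr = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
            logrank_p = float(lr.p_value)
            km_curves = {}
            for name, part in (("high", hi), ("low", lo)):
                kmf = KaplanMeierFitter()
                kmf.fit(part["time"], part["event"])
                km_curves[name] = kmf.survival_function_.reset_index().rename(
                    columns={"timeline": "time", "KM_estimate": "survival"})
            df = surv.copy()
            if covariates is not None:
                for c in covariates.columns:
                    df[c] = pd.to_numeric(covariates[c], errors="coerce").reindex(df.index)
                df = df.dropna()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph = CoxPHFitter()
                    cph.fit(df, duration_col="time", event_col="event")
                cox_summary = cph.summary[["exp(coef)", "exp(coef) lower 95%",
                                           "exp(coef) upper 95%", "p"]].rename(
                    columns={"exp(coef)": "hr", "exp(coef) lower 95%": "hr_lo",
                             "exp(coef) upper 95%": "hr_hi"})
            except Exception as exc:  # pragma: no cover - degenerate fits
                logger.warning("evaluate: multivariate Cox failed (%s)", exc)
        else:
            logger.warning("evaluate: too few events or one group, survival skipped")

    return ScoreEvaluation(scores=scores, auc=auc, roc=roc, cutoff=cutoff,
                           groups=groups, logrank_p=logrank_p,
                           km_curves=km_curves, cox_summary=cox_summary)


# ---------------------------------------------------------------------------
# End-to-end construction
# ---------------------------------------------------------------------------


def build_scoring_system(cohorts: dict[str, tuple[ExpressionTable, PduiTable, ClinicalTable]],
                         gene_sets: GeneSetCollection,
                         survival_cohort: str | None = None,
                         n_perm: int = 1000, seed: int = 0,
                         architecture: str = "linear",
                         split: float = 0.7) -> dict:
    """Run the whole construction on two discovery cohorts.

    ``cohorts`` maps cohort name -> (expression, pdui, clinical); the
    univariate-Cox/LASSO stage runs on ``survival_cohort`` (default: the
    last cohort, i.e. the larger GSE91061-like one); the scorer trains on
    the pooled cohorts with a ``split`` train fraction.  Returns a dict
    with the model, its evaluation on the held-out split, and the full
    selection trail.
    """
    if len(cohorts) < 2:
        raise ValidationError("need two discovery cohorts")
    associations = {}
    for i, (name, (expr, pdui, clinical)) in enumerate(cohorts.items()):
        associations[name] = event_pathway_associations(
            expr, pdui, clinical, gene_sets, n_perm=n_perm, seed=seed + i)
    pairs, candidate_events = screen_immune_events(associations)
    if len(candidate_events) < 2:
        raise ValidationError("screening left fewer than 2 candidate events")

    surv_name = survival_cohort or list(cohorts)[-1]
    _, surv_pdui, surv_clin = cohorts[surv_name]
    feats = _feature_frame(surv_pdui, candidate_events, surv_pdui.sample_ids)
    uni = univariate_cox(feats, surv_clin.data["os_time"], surv_clin.data["os_event"])
    passing = [f for f in uni.index[uni["passed"]]]
    if len(passing) < 2:
        logger.warning("build_scoring_system: <2 events pass univariate Cox; "
                       "keeping the %d candidates", len(candidate_events))
        passing = candidate_events
    lasso = lasso_cox(feats[passing], surv_clin.data["os_time"],
                      surv_clin.data["os_event"], seed=seed)
    selected = list(lasso.index)
    if len(selected) < 2:
        logger.warning("build_scoring_system: LASSO kept %d events; "
                       "falling back to the univariate set", len(selected))
        selected = passing

    # pooled metaAPA cohort
    pooled_pdui = pd.concat(
        [c[1].data.loc[selected] for c in cohorts.values()], axis=1)
    pooled_clin = pd.concat([c[2].data for c in cohorts.values()], axis=0)
    features = pooled_pdui.T
    response = pd.Series(pooled_clin["response"] == "PRCR", index=pooled_clin.index)
    model, split_info = fit_scorer(features, response, architecture=architecture,
                                   split=split, seed=seed)

    test = split_info["test_samples"]
    test_scores = model.score(pooled_pdui[test], impute_missing=True)
    evaluation = evaluate(
        test_scores,
        response=response.loc[test],
        os_time=pooled_clin.loc[test, "os_time"],
        os_event=pooled_clin.loc[test, "os_event"],
    )
    # survival read-out over the full pooled cohort (n = all samples)
    all_scores = model.score(pooled_pdui, impute_missing=True)
    full_evaluation = evaluate(
        all_scores,
        response=response,
        os_time=pooled_clin["os_time"],
        os_event=pooled_clin["os_event"],
    )
    return {
        "model": model,
        "evaluation": evaluation,
        "full_evaluation": full_evaluation,
        "pairs": pairs,
        "candidate_events": candidate_events,
        "univariate": uni,
        "lasso": lasso,
        "split": split_info,
    }
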