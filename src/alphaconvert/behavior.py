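"""Signal-detection and latency indices from recognition trial tables.

Recognition sensitivity d' is z(hit rate) - z(false-alarm rate) under the
standard-normal quantile.  *Associative d'* pools hits and false alarms over
the two congruence conditions (global episodic memory for famous faces);
*semantic d'* is the congruency benefit d'(SCF) - d'(SIF).  Extreme rates
(0 or 1), unavoidable with small trial counts, are handled by the
log-linear correction (x + 0.5) / (n + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .exceptions import (
    DesignError,
    IncompleteDataError,
    InfiniteRateError,
)

CONDITIONS = ("SCF", "SIF")


@dataclass
class RecognitionCounts:
    condition: str  # "SCF", "SIF" or "combined"
    n_targets: int
    n_lures: int
    hits: int
    false_alarms: int

    def __post_init__(self):
        if not (0 <= self.hits <= self.n_targets):
            raise ValueError(f"hits {self.hits} outside [0, {self.n_targets}]")
        if not (0 <= self.false_alarms <= self.n_lures):
            raise ValueError(f"false_alarms {self.false_alarms} outside [0, {self.n_lures}]")


@dataclass
class MemoryScores:
    d_scf: float
    d_sif: float
    associative_d: float
    semantic_d: float
    rt_hits: float
    rt_correct_rejections: float
    omission_rate: float
    success_rate: float


def dprime(counts: RecognitionCounts, correction: str = "log_linear") -> float:
    """Recognition sensitivity z(hit rate) - z(false-alarm rate)."""
    if counts.n_targets < 1 or counts.n_lures < 1:
        raise IncompleteDataError("dprime needs at least one target and one lure trial")
    if correction == "log_linear":
        hr = (counts.hits + 0.5) / (counts.n_targets + 1.0)
        far = (counts.false_alarms + 0.5) / (counts.n_lures + 1.0)
    elif correction == "none":
        hr = counts.hits / counts.n_targets
        far = counts.false_alarms / counts.n_lures
        if hr in (0.0, 1.0) or far in (0.0, 1.0):
            raise InfiniteRateError(
                "hit/false-alarm rate of 0 or 1 gives an infinite d'; "
                "use correction='log_linear'"
            )
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return float(stats.norm.ppf(hr) - stats.norm.ppf(far))


def recognition_counts(trials: pd.DataFrame, condition: str | None = None) -> RecognitionCounts:
    """Tally hits/false alarms from the memory-phase rows of one subject.

    A hit is a correct response to an intact (target) pairing; a false alarm
    is an incorrect *response* to a rearranged (lure) pairing.  Omitted
    trials stay in the denominators but count as neither.
    """
    mem = trials[trials["phase"] == "memory"]
    if condition is not None:
        mem = mem[mem["condition"] == condition]
    if mem.empty:
        raise IncompleteDataError(f"no memory-phase trials for condition {condition!r}")
    targets = mem[mem["is_target"].astype(bool)]
    lures = mem[~mem["is_target"].astype(bool)]
    hits = int((targets["correct"] & targets["responded"]).sum())
    fas = int((~lures["correct"] & lures["responded"]).sum())
    return RecognitionCounts(
        condition=condition or "combined",
        n_targets=len(targets),
        n_lures=len(lures),
        hits=hits,
        false_alarms=fas,
    )


def memory_scores(trials: pd.DataFrame, correction: str = "log_linear") -> MemoryScores:
    """All recognition scores for one subject's trial table."""
    mem = trials[trials["phase"] == "memory"]
    for cond in CONDITIONS:
        if not (mem["condition"] == cond).any():
            raise IncompleteDataError(f"memory-phase trials missing condition {cond!r}")
    per_cond = {c: dprime(recognition_counts(trials, c), correction) for c in CONDITIONS}
    pooled = dprime(recognition_counts(trials), correction)

    targets = mem["is_target"].astype(bool)
    hits_mask = targets & mem["correct"] & mem["responded"]
    cr_mask = ~targets & mem["correct"]
    rt_hits = float(mem.loc[hits_mask, "rt"].mean())
    rt_cr = float(mem.loc[cr_mask, "rt"].mean())
    omission = float((~mem["responded"]).mean())
    success = float((mem["correct"] & mem["responded"]).sum() / len(mem))
    return MemoryScores(
        d_scf=per_cond["SCF"],
        d_sif=per_cond["SIF"],
        associative_d=pooled,
        semantic_d=per_cond["SCF"] - per_cond["SIF"],
        rt_hits=rt_hits,
        rt_correct_rejections=rt_cr,
        omission_rate=omission,
        success_rate=success,
    )


def score_cohort(trials: pd.DataFrame, correction: str = "log_linear") -> pd.DataFrame:
    """One MemoryScores row per subject."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=False):
        s = memory_scores(sub, correction)
        rows.append({"subject_id": sid, **s.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level GLM


def group_glm(
    outcome: np.ndarray,
    group: np.ndarray,
    within: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    group_order: list | None = None,
):
    """Between/within ANCOVA on per-subject values.

    ``outcome`` is (n,) for a purely between-subjects analysis or (n, 2) with
    one column per level of the 2-level within-subjects factor (hemisphere,
    congruence).  The mixed design is handled by the exact summary-statistic
    split: subject means carry the between-group effect, subject differences
    carry the within main effect and the group x within interaction — exact
    for two within-levels.  Nuisance covariates are mean-centered and
    partialled in every part.  Returns a dict of effects
    ``{name: {"F", "df1", "df2", "p"}}`` plus Bonferroni-corrected pairwise
    group contrasts on the between part.
    """
    outcome = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    levels = group_order or list(pd.unique(group))
    if len(levels) < 2:
        raise DesignError("group_glm needs at least 2 groups")
    for g in levels:
        if (group == g).sum() < 3:
            raise DesignError(f"group {g!r} has fewer than 3 subjects")

    cov = None
    if nuisance is not None:
        cov = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if cov.shape[0] != len(group):
            cov = cov.T
        cov = cov - cov.mean(axis=0)
        cov = cov[:, cov.std(axis=0) > 0]  # constant covariates carry no information
        if cov.shape[1] == 0:
            cov = None

    def _fit(y):
        df = pd.DataFrame({"y": y, "group": pd.Categorical(group, categories=levels)})
        terms = ["C(group)"]
        if cov is not None:
            for j in range(cov.shape[1]):
                df[f"cov{j}"] = cov[:, j]
                terms.append(f"cov{j}")
        model = smf.ols("y ~ " + " + ".join(terms), data=df).fit()
        if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
            raise DesignError("rank-deficient design: aliased group/covariate terms")
        anova = sm.stats.anova_lm(model, typ=2)
        return model, anova

    effects = {}
    y_between = outcome if outcome.ndim == 1 else outcome.mean(axis=1)
    model_b, anova_b = _fit(y_between)
    row = anova_b.loc["C(group)"]
    resid = anova_b.loc["Residual"]
    effects["group"] = {
        "F": float(row["F"]),
        "df1": float(row["df"]),
        "df2": float(resid["df"]),
        "p": float(row["PR(>F)"]),
    }

    if outcome.ndim == 2:
        d = outcome[:, 0] - outcome[:, 1]
        model_w, anova_w = _fit(d)
        # within main effect: unweighted grand mean of the differences
        # (intercept + average of the treatment-coded group offsets)
        vec = np.zeros(len(model_w.params))
        for k, name in enumerate(model_w.params.index):
            if name == "Intercept":
                vec[k] = 1.0
            elif name.startswith("C(group)[T."):
                vec[k] = 1.0 / len(levels)
        t_int = model_w.t_test(vec)
        F_w = float(np.squeeze(t_int.tvalue)) ** 2
        effects["within"] = {
            "F": F_w,
            "df1": 1.0,
            "df2": float(model_w.df_resid),
            "p": float(np.squeeze(t_int.pvalue)),
        }
        row = anova_w.loc["C(group)"]
        effects["group_x_within"] = {
            "F": float(row["F"]),
            "df1": float(row["df"]),
            "df2": float(anova_w.loc["Residual"]["df"]),
            "p": float(row["PR(>F)"]),
        }

    # Bonferroni pairwise contrasts on adjusted between-part means
    pairs = {}
    names = list(model_b.params.index)
    n_pairs = len(levels) * (len(levels) - 1) // 2
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            vec = np.zeros(len(names))
            for k, name in enumerate(names):
                if name == f"C(group)[T.{levels[i]}]":
                    vec[k] = 1.0
                if name == f"C(group)[T.{levels[j]}]":
                    vec[k] = -1.0
            tt = model_b.t_test(vec)
            pairs[(levels[i], levels[j])] = {
                "t": float(np.squeeze(tt.tvalue)),
                "p_bonferroni": float(min(1.0, np.squeeze(tt.pvalue) * n_pairs)),
            }
    return {"effects": effects, "pairwise": pairs}
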