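"""Cross-validation harnesses, ROC metrics and agreement statistics.

Classifiers are scored per held-out subject (leave-one-subject-out, LOSO)
or per stratified fold. The operating point is the threshold of equal
sensitivity and specificity; discrimination is summarised by the
trapezoidal AUC with Hanley-McNeil standard errors. Amplitude agreement
across clinical severity groups uses Shapiro-Wilk normality checks, the
Kruskal-Wallis H test and Dunn's post-hoc pairwise comparisons; constancy
agreement uses the Pearson correlation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import models as _models
from .preprocessing import WindowSet

__all__ = [
    "FoldResult", "EvalReport", "AgreementReport", "loso_split",
    "stratified_kfold_split", "roc_auc", "equal_sens_spec_threshold",
    "hanley_auc_se", "auc_diff_significance", "run_loso",
    "run_stratified_kfold", "dunn_test", "amplitude_agreement",
    "constancy_correlation",
]


@dataclass
class FoldResult:
    held_out_id: str
    task: str
    sensitivity: float
    specificity: float
    auc: float
    operating_threshold: float
    repeat: int = 0


@dataclass
class EvalReport:
    """Per-fold metrics with mean/std summaries across subjects and repeats."""
    results: list  # of FoldResult
    scheme: str = "loso"
    n_repeats: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        return (df.groupby("task")[["sensitivity", "specificity", "auc"]]
                  .agg(["mean", "std"]))

    def per_subject(self) -> pd.DataFrame:
        """Mean (std over repeats) per held-out subject and task."""
        df = self.to_frame()
        return (df.groupby(["held_out_id", "task"])[["auc", "sensitivity", "specificity"]]
                  .agg(["mean", "std"]))

    def to_json_obj(self) -> dict:
        summary = {}
        for task, row in self.summary().iterrows():
            summary[task] = {f"{metric}_{stat}": (None if pd.isna(v) else float(v))
                             for (metric, stat), v in row.items()}
        return {
            "scheme": self.scheme,
            "n_repeats": self.n_repeats,
            "folds": [vars(r) for r in self.results],
            "summary": summary,
        }


def loso_split(subject_ids) -> list:
    """One (train subjects, test subject) fold per subject.

    A subject-level partition: windows of the held-out subject never occur
    in training, so 50%-overlapping windows cannot straddle the split.
    """
    subjects = list(dict.fromkeys(subject_ids))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    return [([s for s in subjects if s != held_out], held_out)
            for held_out in subjects]


def stratified_kfold_split(labels, k: int = 10, seed: int = 0) -> list:
    """Seeded stratified folds preserving per-class proportions.

    Returns a list of (train_idx, test_idx) pairs.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} windows < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC (ties at midrank; equals Mann-Whitney U/(n1*n2))."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def equal_sens_spec_threshold(scores, labels):
    """Operating point where sensitivity and specificity cross.

    Candidate thresholds are the midpoints between consecutive sorted
    unique scores (plus one below the minimum and one above the maximum);
    a sample is predicted positive when score >= threshold. Among
    candidates the one minimising |sens - spec| wins, ties resolved toward
    higher specificity (then the higher threshold).
    Returns (threshold, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    pred = scores[None, :] >= candidates[:, None]       # (T, n)
    sens = (pred & labels).sum(axis=1) / n_pos
    spec = (~pred & ~labels).sum(axis=1) / n_neg
    gap = np.abs(sens - spec)
    # lexicographic: min gap, then max specificity, then max threshold
    order = np.lexsort((candidates, spec, -gap))
    best = order[-1]
    return float(candidates[best]), float(sens[best]), float(spec[best])


def hanley_auc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC estimate."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must be in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes need at least one sample")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_diff_significance(auc1, n_pos1, n_neg1, auc2, n_pos2, n_neg2):
    """Normal z-test for the difference of two independent AUCs.

    Returns (z, two-sided p).
    """
    se = np.sqrt(hanley_auc_se(auc1, n_pos1, n_neg1) ** 2 +
                 hanley_auc_se(auc2, n_pos2, n_neg2) ** 2)
    if se == 0:
        raise ValueError("zero standard error; AUC difference test undefined")
    z = (auc1 - auc2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


_TASK_LABELS = {"context": "rest_label", "tremor": "tremor_label"}


def _fold_metrics(probs: dict, ws_test: WindowSet, held_out: str, repeat: int,
                  tasks) -> list:
    out = []
    for task in tasks:
        label = getattr(ws_test, _TASK_LABELS[task])
        valid = label >= 0
        y = label[valid]
        if len(np.unique(y)) < 2:
            continue  # e.g. a tremor-free held-out subject: no tremor metrics
        s = probs[task][valid]
        thr, sens, spec = equal_sens_spec_threshold(s, y)
        out.append(FoldResult(held_out_id=held_out, task=task,
                              sensitivity=sens, specificity=spec,
                              auc=roc_auc(s, y), operating_threshold=thr,
                              repeat=repeat))
    return out


def _train_and_score(spec, ws_train: WindowSet, ws_test: WindowSet,
                     config: _models.TrainConfig, representation: str):
    multitask = set(spec.head_names) == {"context", "tremor"}
    if multitask:
        # windows valid for *both* heads (conservative intersection)
        keep = (ws_train.rest_label >= 0) & (ws_train.tremor_label >= 0)
        sub = ws_train.subset(keep)
        labels = {"context": sub.rest_label, "tremor": sub.tremor_label}
        model = _models.train(spec, sub.features(representation), labels, config)
        probs = _models.predict_proba(model, ws_test.features(representation))
        tasks = ("context", "tremor")
    else:
        raise ValueError("run_loso/run_stratified_kfold expect a multitask spec; "
                         "train single-output models directly with models.train")
    return probs, tasks


def run_loso(spec, ws: WindowSet, config: _models.TrainConfig,
             n_repeats: int = 6, representation: str | None = None) -> EvalReport:
    """Leave-one-subject-out evaluation of a multitask spec, repeated
    ``n_repeats`` times with distinct deterministic training seeds.

    Subjects whose held-out windows contain a single class for a task
    (e.g. tremor-free subjects for the tremor head) are excluded from that
    task's metrics.
    """
    if representation is None:
        representation = "fft" if tuple(spec.input_shape) == (64, 1) else "raw"
    results = []
    folds = loso_split(ws.subject_id)
    for repeat in range(n_repeats):
        for fold_idx, (train_subjects, held_out) in enumerate(folds):
            test_mask = ws.subject_id == held_out
            ws_train = ws.subset(~test_mask)
            ws_test = ws.subset(test_mask)
            fold_config = _models.TrainConfig(
                **{**vars(config),
                   "seed": (config.seed * 10007 + repeat * 101 + fold_idx) % (2 ** 31)})
            probs, tasks = _train_and_score(spec, ws_train, ws_test, fold_config,
                                            representation)
            results.extend(_fold_metrics(probs, ws_test, held_out, repeat, tasks))
    return EvalReport(results=results, scheme="loso", n_repeats=n_repeats)


def run_stratified_kfold(spec, ws: WindowSet, config: _models.TrainConfig,
                         k: int = 10, n_repeats: int = 1,
                         representation: str | None = None) -> EvalReport:
    """Stratified k-fold evaluation on jointly-valid windows (stratified on
    the combined context/tremor class)."""
    if representation is None:
        representation = "fft" if tuple(spec.input_shape) == (64, 1) else "raw"
    keep = (ws.rest_label >= 0) & (ws.tremor_label >= 0)
    wsv = ws.subset(keep)
    strata = wsv.rest_label * 2 + wsv.tremor_label
    results = []
    for repeat in range(n_repeats):
        folds = stratified_kfold_split(strata, k=k, seed=config.seed + repeat)
        for fold_idx, (train_idx, test_idx) in enumerate(folds):
            mask = np.zeros(len(wsv), dtype=bool)
            mask[test_idx] = True
            fold_config = _models.TrainConfig(
                **{**vars(config),
                   "seed": (config.seed * 10007 + repeat * 101 + fold_idx) % (2 ** 31)})
            probs, tasks = _train_and_score(spec, wsv.subset(~mask), wsv.subset(mask),
                                            fold_config, representation)
            results.extend(_fold_metrics(probs, wsv.subset(mask), f"fold_{fold_idx}",
                                         repeat, tasks))
    return EvalReport(results=results, scheme=f"stratified{k}", n_repeats=n_repeats)


@dataclass
class AgreementReport:
    kruskal_h: float
    kruskal_p: float
    shapiro_p: dict            # group -> p
    dunn_p: pd.DataFrame       # symmetric pairwise p matrix
    pearson_r: float | None = None
    pearson_p: float | None = None


def dunn_test(groups: dict, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc pairwise z-tests on rank sums after Kruskal-Wallis.

    Uses the tie-corrected pooled rank variance; ``adjust`` is
    ``bonferroni`` (default), ``holm`` or ``none``. Returns a symmetric
    DataFrame of p-values with 1.0 on the diagonal.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    all_vals = np.concatenate(values)
    n_total = len(all_vals)
    ranks = stats.rankdata(all_vals)
    mean_ranks, sizes = {}, {}
    pos = 0
    for name, vals in zip(names, values):
        mean_ranks[name] = ranks[pos:pos + len(vals)].mean()
        sizes[name] = len(vals)
        pos += len(vals)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    if base_var <= 0:
        raise ValueError("degenerate data: all observations tied")

    pairs = list(itertools.combinations(names, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * stats.norm.sf(abs(z)))
    raw = np.asarray(raw)
    m = len(pairs)
    if adjust == "bonferroni":
        adj = np.minimum(raw * m, 1.0)
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = np.empty(m)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, raw[idx] * (m - rank_i))
            adj[idx] = min(running, 1.0)
    elif adjust == "none":
        adj = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def amplitude_agreement(la_values, clinical_scores, adjust: str = "bonferroni") -> AgreementReport:
    """Agreement between per-visit acceleration levels and ordinal clinical
    severity scores: Shapiro-Wilk per group, Kruskal-Wallis across groups,
    Dunn pairwise post-hoc."""
    la_values = np.asarray(la_values, dtype=float)
    clinical_scores = np.asarray(clinical_scores)
    groups = {int(s): la_values[clinical_scores == s]
              for s in np.unique(clinical_scores)}
    if len(groups) < 2 or any(len(v) < 3 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 3 visits each")
    shapiro_p = {}
    for name, vals in groups.items():
        if np.ptp(vals) == 0:
            raise ValueError(f"group {name} has zero variance")
        shapiro_p[name] = float(stats.shapiro(vals).pvalue)
    h, p = stats.kruskal(*groups.values())
    dunn = dunn_test(groups, adjust=adjust)
    return AgreementReport(kruskal_h=float(h), kruskal_p=float(p),
                           shapiro_p=shapiro_p, dunn_p=dunn)


def constancy_correlation(estimated_pct, reference_pct):
    """Pearson correlation between estimated and reference constancy.

    Returns (r, two-sided p). Constant vectors make the correlation
    undefined and raise.
    """
    est = np.asarray(estimated_pct, dtype=float)
    ref = np.asarray(reference_pct, dtype=float)
    if len(est) != len(ref) or len(est) < 3:
        raise ValueError("need >= 3 paired visits")
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        raise ValueError("constant input vector: correlation undefined")
    res = stats.pearsonr(est, ref)
    return float(res.statistic), float(res.pvalue)
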