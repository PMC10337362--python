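"""Feature assembly, ANOVA screening, cross-validated classification and
grouped feature importance.

The evaluation protocol mirrors the study design: stratified 5-fold
cross-validation in which each fold serves once as the test set, with the
template re-selected per fold from the *training* healthy controls so no
test-fold information leaks into the reference; reported metrics are fold
means.  The reference classifier is a random forest with library-default
hyperparameters and a pinned seed; SVC, AdaBoost, gradient boosting and a
LightGBM-style booster are available for comparison.  Feature importance is
the per-feature mean absolute attribution (tree-path attribution for tree
ensembles, permutation importance otherwise), additively aggregated into
named feature families.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from . import kinematics, template
from .core import BLOCK_KEYS, INTERACTION_FIELDS, SubjectRecord, block_key_str
from .template import (
    DEFAULT_CODEBOOK_SIZE,
    DEFAULT_RADIUS,
    DEFAULT_SIGMA,
    DEFAULT_SUBSET_SIZE,
    KeyPointSequence,
    TemplateSet,
    extract_keypoints,
    select_template,
    template_features,
)

#: impairment ordering used to fix the positive class (the more impaired side)
GROUP_ORDER = {"HC": 0, "MCI": 1, "AD": 2}

TASKS: dict[str, tuple[str, str]] = {
    "HCvsMCI": ("HC", "MCI"),
    "HCvsAD": ("HC", "AD"),
    "MCIvsAD": ("MCI", "AD"),
}
AD_VS_OTHERS = "ADvsOthers"

MODELS = ("svc", "adaboost", "random_forest", "gbdt", "lightgbm")

DEMOGRAPHIC_COLUMNS = ("sex", "age", "education")


def normalize_task(task: str) -> str:
    key = task.replace("-", "").replace("_", "").lower()
    for name in (*TASKS, AD_VS_OTHERS):
        if name.lower() == key:
            return name
    raise ValueError(f"unknown task {task!r}")


def feature_group(name: str) -> str:
    """Map a feature column to its named family (for grouped importance)."""
    if name.startswith("missingindicator_"):
        name = name[len("missingindicator_"):]
    prefixes = [
        ("tmpl_vqw_", "VQ with relative weights"),
        ("tmpl_vq_", "VQ without weights"),
        ("tmpl_dtwd_", "DTWD"),
        ("completion_", "completion time"),
        ("tdiff_", "completion time"),
        ("tratio_", "completion time"),
        ("prep_", "preparation time"),
        ("exec_", "execution time"),
        ("pmean_", "averaged write pressure"),
        ("pmin_", "minimal write pressure"),
        ("pmax_", "maximal write pressure"),
        ("jerk_", "jerk"),
    ]
    for pre, grp in prefixes:
        if name.startswith(pre):
            return grp
    if name in DEMOGRAPHIC_COLUMNS:
        return "demographics"
    if name in INTERACTION_FIELDS:
        return "interactive behaviors"
    return "other"


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def subject_seed(subject_id: str, seed: int) -> int:
    """Stable per-subject seed, independent of record order."""
    return (zlib.crc32(subject_id.encode()) ^ (seed * 2654435761)) & 0x7FFFFFFF


def kinematic_row(record: SubjectRecord) -> dict[str, float]:
    """Per-block kinematic features plus the A2/B2 cross-block contrasts."""
    row: dict[str, float] = {}
    for part, block in BLOCK_KEYS:
        suf = block_key_str(part, block)
        traj = record.trajectories.get((part, block))
        if traj is None:
            bf = dict.fromkeys(
                ("completion_time", "preparation_time", "execution_time",
                 "pressure_mean", "pressure_min", "pressure_max", "jerk"),
                np.nan,
            )
        else:
            bf = kinematics.block_features(traj).as_dict()
        row[f"completion_{suf}"] = bf["completion_time"]
        row[f"prep_{suf}"] = bf["preparation_time"]
        row[f"exec_{suf}"] = bf["execution_time"]
        row[f"pmean_{suf}"] = bf["pressure_mean"]
        row[f"pmin_{suf}"] = bf["pressure_min"]
        row[f"pmax_{suf}"] = bf["pressure_max"]
        row[f"jerk_{suf}"] = bf["jerk"]
    t_a2, t_b2 = row["completion_A2"], row["completion_B2"]
    if np.isnan(t_a2) or np.isnan(t_b2):
        row["tdiff_A2B2"] = np.nan
        row["tratio_A2B2"] = np.nan
    else:
        row["tdiff_A2B2"] = kinematics.time_difference(t_a2, t_b2)
        row["tratio_A2B2"] = kinematics.time_ratio(t_a2, t_b2)
    return row


def extract_all_keypoints(
    records: list[SubjectRecord],
    k: int = DEFAULT_CODEBOOK_SIZE,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
) -> dict[tuple[str, tuple[str, int]], KeyPointSequence]:
    """Key points for every (subject, block); seeded per subject so the
    result is deterministic and independent of record order."""
    out = {}
    for rec in records:
        for key, traj in rec.trajectories.items():
            out[(rec.subject_id, key)] = extract_keypoints(
                traj, k=k, sigma=sigma, seed=subject_seed(rec.subject_id, seed)
            )
    return out


def fit_templates(
    hc_records: list[SubjectRecord],
    subset_size: int = DEFAULT_SUBSET_SIZE,
    seed: int = 0,
    k: int = DEFAULT_CODEBOOK_SIZE,
    sigma: float = DEFAULT_SIGMA,
    method: str = "fast",
    radius: int = DEFAULT_RADIUS,
    keypoints: dict | None = None,
    _dtwd_cache: dict | None = None,
) -> TemplateSet:
    """Select one reference per (part, block) from healthy controls and
    extract its key points."""
    ts = TemplateSet(seed=seed, codebook_size=k, sigma=sigma)
    for key in BLOCK_KEYS:
        pool = [
            rec.trajectories[key]
            for rec in hc_records
            if rec.group == "HC" and key in rec.trajectories
        ]
        if not pool:
            continue
        cache = None if _dtwd_cache is None else _dtwd_cache.setdefault(key, {})
        ref = select_template(pool, subset_size=subset_size, seed=seed,
                              method=method, radius=radius, _dtwd_cache=cache)
        if keypoints is not None and (ref.subject_id, key) in keypoints:
            kp = keypoints[(ref.subject_id, key)]
        else:
            kp = extract_keypoints(ref, k=k, sigma=sigma,
                                   seed=subject_seed(ref.subject_id, seed))
        ts.keypoints[key] = kp
    return ts


def assemble_feature_table(
    records: list[SubjectRecord],
    templates: TemplateSet | None = None,
    feature_set: str = "proposed",
    followup_mode: bool = False,
    keypoints: dict | None = None,
    k: int = DEFAULT_CODEBOOK_SIZE,
    sigma: float = DEFAULT_SIGMA,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the subject x feature matrix (index: subject_id; ``group``
    column holds the label, NaN-free only for labelled rows).

    ``conventional`` = completion times + demographics + examiner
    interaction counts (the paper-based test's information).  ``proposed`` =
    all kinematic, cross-block and template features plus demographics,
    excluding interaction counts.  ``all`` = everything.  Follow-up mode
    additionally drops identity-related columns (sex, age, education), as
    re-assessed subjects would otherwise be recognizable to the model.
    """
    if feature_set not in ("conventional", "proposed", "all"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    need_templates = feature_set in ("proposed", "all")
    if need_templates and templates is None:
        raise ValueError(f"feature_set {feature_set!r} requires templates")

    rows = []
    for rec in records:
        row: dict[str, float] = {"group": rec.group}
        kin = kinematic_row(rec)
        if feature_set == "conventional":
            row.update({c: kin[c] for c in kin if c.startswith("completion_")})
        else:
            row.update(kin)
            for key in BLOCK_KEYS:
                suf = block_key_str(*key)
                tf = None
                if key in templates.keypoints and key in rec.trajectories:
                    kp = None
                    if keypoints is not None:
                        kp = keypoints.get((rec.subject_id, key))
                    if kp is None:
                        kp = extract_keypoints(
                            rec.trajectories[key], k=k, sigma=sigma,
                            seed=subject_seed(rec.subject_id, seed),
                        )
                    tf = template_features(templates.keypoints[key], kp)
                row[f"tmpl_dtwd_{suf}"] = np.nan if tf is None else tf.dtwd
                row[f"tmpl_vq_{suf}"] = np.nan if tf is None else tf.vq_unweighted
                row[f"tmpl_vqw_{suf}"] = np.nan if tf is None else tf.vq_weighted
        if not followup_mode:
            for c in DEMOGRAPHIC_COLUMNS:
                v = getattr(rec, c)
                row[c] = np.nan if v is None else float(v)
        if feature_set in ("conventional", "all"):
            for c in INTERACTION_FIELDS:
                v = rec.interaction_counts.get(c)
                row[c] = np.nan if v is None else float(v)
        rows.append(pd.Series(row, name=rec.subject_id))
    table = pd.DataFrame(rows)
    table.index.name = "subject_id"
    return table


# ---------------------------------------------------------------------------
# ANOVA screening
# ---------------------------------------------------------------------------

def anova_screen(table: pd.DataFrame, label_col: str = "group",
                 bh_correct: bool = False) -> pd.DataFrame:
    """Per-feature one-way ANOVA F-tests for every pair of groups.

    Missing values are dropped listwise per feature.  Returns a frame
    indexed by feature with ``F_<g1>_vs_<g2>`` and ``p_<g1>_vs_<g2>``
    columns; a pair where both groups have zero variance yields NaN.  With
    ``bh_correct`` (an extension beyond the raw screen), adds
    Benjamini-Hochberg adjusted columns ``p_bh_*``.
    """
    groups = [g for g in table[label_col].dropna().unique()]
    groups.sort(key=lambda g: GROUP_ORDER.get(g, 99))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    features = [c for c in table.columns if c != label_col]
    out = pd.DataFrame(index=pd.Index(features, name="feature"))
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            g1, g2 = groups[i], groups[j]
            fcol, pcol = [], []
            for feat in features:
                a = table.loc[table[label_col] == g1, feat].dropna().to_numpy(float)
                b = table.loc[table[label_col] == g2, feat].dropna().to_numpy(float)
                if len(a) < 2 or len(b) < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
                    fcol.append(np.nan)
                    pcol.append(np.nan)
                    continue
                F, p = stats.f_oneway(a, b)
                fcol.append(float(F))
                pcol.append(float(p))
            out[f"F_{g1}_vs_{g2}"] = fcol
            out[f"p_{g1}_vs_{g2}"] = pcol
            if bh_correct:
                p = np.asarray(pcol, dtype=float)
                adj = np.full_like(p, np.nan)
                ok = ~np.isnan(p)
                if ok.any():
                    adj[ok] = stats.false_discovery_control(p[ok])
                out[f"p_bh_{g1}_vs_{g2}"] = adj
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def make_model(name: str, seed: int = 0):
    """Library-default classifiers with pinned seeds."""
    if name == "svc":
        return SVC(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if name == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbosity=-1)
    raise ValueError(f"unknown model {name!r}; expected one of {MODELS}")


def _make_pipeline(model_name: str, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", add_indicator=True,
                                     keep_empty_features=True)),
            ("clf", make_model(model_name, seed)),
        ]
    )


def _scores(pipe: Pipeline, X: pd.DataFrame) -> np.ndarray:
    clf = pipe.named_steps["clf"]
    Xi = pipe.named_steps["impute"].transform(X)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(Xi)[:, list(clf.classes_).index(1)]
    return clf.decision_function(Xi)


def _binary_metrics(y_true, y_pred, scores) -> dict[str, float]:
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    auc = roc_auc_score(y_true, scores) if len(np.unique(y_true)) == 2 else np.nan
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "auc": float(auc),
        "sensitivity": float(sens),
        "specificity": float(spec),
    }


def _task_labels(records: list[SubjectRecord], task: str):
    """(task records, binary labels) — positive class is the more impaired."""
    task = normalize_task(task)
    if task == AD_VS_OTHERS:
        sel = [r for r in records if r.group is not None]
        y = np.array([1 if r.group == "AD" else 0 for r in sel])
    else:
        g0, g1 = TASKS[task]
        sel = [r for r in records if r.group in (g0, g1)]
        y = np.array([1 if r.group == g1 else 0 for r in sel])
    return sel, y


def table_labels(table: pd.DataFrame, task: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Subset a feature table to a task and return (X, binary y)."""
    task = normalize_task(task)
    if task == AD_VS_OTHERS:
        sub = table[table["group"].notna()]
        y = (sub["group"] == "AD").to_numpy().astype(int)
    else:
        g0, g1 = TASKS[task]
        sub = table[table["group"].isin([g0, g1])]
        y = (sub["group"] == g1).to_numpy().astype(int)
    return sub.drop(columns=["group"]), y


@dataclass
class ClassificationReport:
    """Fold-mean metrics of one task x model evaluation."""

    task: str
    model: str
    seed: int
    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    per_fold: pd.DataFrame = field(repr=False, default=None)
    fold_templates: list[dict] = field(repr=False, default_factory=list)
    fold_test_subjects: list[list[str]] = field(repr=False, default_factory=list)

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "model": self.model,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def _report_from_folds(task, model, seed, fold_rows, fold_templates,
                       fold_test_subjects=()):
    per_fold = pd.DataFrame(fold_rows)
    means = per_fold[["accuracy", "auc", "sensitivity", "specificity"]].mean()
    return ClassificationReport(
        task=task, model=model, seed=seed,
        accuracy=float(means["accuracy"]), auc=float(means["auc"]),
        sensitivity=float(means["sensitivity"]),
        specificity=float(means["specificity"]),
        per_fold=per_fold, fold_templates=fold_templates,
        fold_test_subjects=list(fold_test_subjects),
    )


def cross_validate(
    records: list[SubjectRecord],
    task: str,
    model: str = "random_forest",
    feature_set: str = "proposed",
    folds: int = 5,
    seed: int = 0,
    subset_size: int = DEFAULT_SUBSET_SIZE,
    k: int = DEFAULT_CODEBOOK_SIZE,
    sigma: float = DEFAULT_SIGMA,
    dtw_method: str = "fast",
    radius: int = DEFAULT_RADIUS,
    keypoints: dict | None = None,
) -> ClassificationReport:
    """End-to-end stratified k-fold cross-validation from raw records.

    Per fold, the template is re-selected from healthy controls *outside*
    the test fold; trajectory key points (template-independent) are
    precomputed once (pass ``keypoints`` from
    :func:`extract_all_keypoints` to reuse them across calls).
    Deterministic for fixed seeds.
    """
    task = normalize_task(task)
    sel, y = _task_labels(records, task)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")

    need_templates = feature_set in ("proposed", "all")
    if need_templates and keypoints is None:
        keypoints = extract_all_keypoints(records, k=k, sigma=sigma, seed=seed)
    hc_all = [r for r in records if r.group == "HC"]
    dtwd_cache: dict = {}

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_seed_rng = np.random.default_rng(seed)
    fold_rows, fold_templates, fold_test_subjects = [], [], []
    for train_idx, test_idx in skf.split(np.zeros(len(sel)), y):
        fold_seed = int(fold_seed_rng.integers(0, 2**31 - 1))
        test_ids = {sel[i].subject_id for i in test_idx}
        fold_test_subjects.append(sorted(test_ids))
        templates = None
        if need_templates:
            hc_pool = [r for r in hc_all if r.subject_id not in test_ids]
            templates = fit_templates(
                hc_pool, subset_size=subset_size, seed=fold_seed,
                k=k, sigma=sigma, method=dtw_method, radius=radius,
                keypoints=keypoints, _dtwd_cache=dtwd_cache,
            )
            fold_templates.append(
                {key: kp.subject_id for key, kp in templates.keypoints.items()}
            )
        train_recs = [sel[i] for i in train_idx]
        test_recs = [sel[i] for i in test_idx]
        tab_train = assemble_feature_table(
            train_recs, templates, feature_set, keypoints=keypoints,
            k=k, sigma=sigma, seed=seed,
        )
        tab_test = assemble_feature_table(
            test_recs, templates, feature_set, keypoints=keypoints,
            k=k, sigma=sigma, seed=seed,
        )
        X_train = tab_train.drop(columns=["group"])
        X_test = tab_test.drop(columns=["group"])
        pipe = _make_pipeline(model, seed)
        pipe.fit(X_train, y[train_idx])
        y_pred = pipe.predict(X_test)
        fold_rows.append(_binary_metrics(y[test_idx], y_pred, _scores(pipe, X_test)))
    return _report_from_folds(task, model, seed, fold_rows, fold_templates,
                              fold_test_subjects)


def cross_validate_table(
    table: pd.DataFrame,
    task: str,
    model: str = "random_forest",
    folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold cross-validation over a precomputed feature table
    (template features, if present, are taken as fixed columns)."""
    task = normalize_task(task)
    X, y = table_labels(table, task)
    counts = np.bincount(y)
    if len(counts) < 2 or counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_rows = []
    for train_idx, test_idx in skf.split(X, y):
        pipe = _make_pipeline(model, seed)
        pipe.fit(X.iloc[train_idx], y[train_idx])
        y_pred = pipe.predict(X.iloc[test_idx])
        fold_rows.append(
            _binary_metrics(y[test_idx], y_pred, _scores(pipe, X.iloc[test_idx]))
        )
    return _report_from_folds(task, model, seed, fold_rows, [])


@dataclass
class FittedModel:
    """A pipeline fitted on one task's training table."""

    pipeline: Pipeline
    columns: list[str]
    task: str
    model: str
    seed: int


def fit_model(table: pd.DataFrame, task: str, model: str = "random_forest",
              seed: int = 0) -> FittedModel:
    task = normalize_task(task)
    X, y = table_labels(table, task)
    pipe = _make_pipeline(model, seed)
    pipe.fit(X, y)
    return FittedModel(pipeline=pipe, columns=list(X.columns), task=task,
                       model=model, seed=seed)


def evaluate_holdout(fitted: FittedModel, holdout: pd.DataFrame) -> ClassificationReport:
    """Score an untouched holdout table with a trained model.

    The holdout's feature columns must match the training columns (e.g.
    both assembled in follow-up mode).  For the AD-vs-others task, HC and
    MCI rows are relabelled as the negative class.
    """
    X, y = table_labels(holdout, fitted.task)
    if list(X.columns) != fitted.columns:
        raise ValueError("holdout columns do not match training columns")
    y_pred = fitted.pipeline.predict(X)
    m = _binary_metrics(y, y_pred, _scores(fitted.pipeline, X))
    return ClassificationReport(
        task=fitted.task, model=fitted.model, seed=fitted.seed,
        per_fold=pd.DataFrame([m]), **m,
    )


# ---------------------------------------------------------------------------
# grouped feature importance
# ---------------------------------------------------------------------------

def _is_classifier_tree_ensemble(clf) -> bool:
    if hasattr(clf, "tree_"):
        return getattr(clf, "n_classes_", 1) >= 2
    ests = getattr(clf, "estimators_", None)
    if ests is None or len(ests) == 0:
        return False
    flat = list(np.ravel(np.asarray(ests, dtype=object)))
    return all(hasattr(e, "tree_") and getattr(e, "n_classes_", 1) >= 2 for e in flat)


def _tree_path_attributions(forest, X: np.ndarray) -> np.ndarray:
    """Per-sample signed feature contributions along tree decision paths.

    For each tree, a sample's predicted positive-class probability is
    decomposed into the root value plus, at every split on its path, the
    change in node value attributed to the split feature; contributions are
    averaged over trees.
    """
    n, p = X.shape
    contrib = np.zeros((n, p))
    trees = getattr(forest, "estimators_", [forest])
    for est in trees:
        tt = est.tree_
        val = tt.value[:, 0, :]
        prob = val[:, -1] / val.sum(axis=1)
        left, right = tt.children_left, tt.children_right
        feat, thr = tt.feature, tt.threshold
        for i in range(n):
            node = 0
            while left[node] != -1:
                f = feat[node]
                nxt = left[node] if X[i, f] <= thr[node] else right[node]
                contrib[i, f] += prob[nxt] - prob[node]
                node = nxt
    return contrib / len(trees)


@dataclass
class ImportanceReport:
    """Mean absolute attribution per feature, aggregated by family.

    ``per_group`` entries are exact sums of their member features, so
    family importance is additive.
    """

    per_feature: pd.Series
    per_group: pd.Series
    backend: str


def grouped_importance(
    fitted: FittedModel,
    table: pd.DataFrame,
    grouping=None,
    backend: str = "auto",
    seed: int = 0,
) -> ImportanceReport:
    """Per-feature mean |attribution| and additive family aggregates.

    ``backend='tree'`` uses tree-path attribution (random forests and
    single trees); ``'permutation'`` uses seeded permutation importance on
    accuracy; ``'auto'`` picks tree when available.  ``grouping`` maps
    feature name -> family name (default: :func:`feature_group`).
    """
    if grouping is None:
        grouping = feature_group
    X, y = table_labels(table, fitted.task)
    imputer = fitted.pipeline.named_steps["impute"]
    clf = fitted.pipeline.named_steps["clf"]
    Xi = imputer.transform(X)
    names = list(imputer.get_feature_names_out(X.columns))

    is_tree = _is_classifier_tree_ensemble(clf)
    if backend == "tree" and not is_tree:
        raise ValueError("tree backend requires an ensemble of classifier trees")
    if backend not in ("auto", "tree", "permutation"):
        raise ValueError(f"unknown backend {backend!r}")
    if is_tree and backend in ("auto", "tree"):
        contrib = _tree_path_attributions(clf, np.asarray(Xi, dtype=float))
        vals = np.abs(contrib).mean(axis=0)
        used = "tree"
    else:
        res = permutation_importance(
            clf, Xi, y, n_repeats=10, random_state=seed, scoring="accuracy"
        )
        vals = np.abs(res.importances_mean)
        used = "permutation"

    per_feature = pd.Series(vals, index=names).sort_values(ascending=False)
    fam = pd.Series({n: grouping(n) if callable(grouping) else grouping.get(n, "other")
                     for n in names})
    per_group = per_feature.groupby(fam).sum().sort_values(ascending=False)
    return ImportanceReport(per_feature=per_feature, per_group=per_group,
                            backend=used)
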