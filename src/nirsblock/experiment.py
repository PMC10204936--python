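"""Training schemes, grid search, macro-F1 scoring and model comparison.

Two evaluation schemes mirror how BCI generalisation is reported:

* ``mixed`` - every subject contributes training data; one collection
  session (the last run of each subject) is held out for testing.
* ``subject_independent`` - leave-one-subject-out: the test subject's data
  never appears in training (no calibration session for a new user).

Three model + data-structure combinations are compared: the
spatial-temporal 3D CNN on the Block images, the same 3D CNN on the
non-spatial S-by-D arrangement, and the per-channel temporal 1D CNN on the
Flat matrix.  Mirror-flip augmentation applies only to Block training
folds.  Scores are macro-averaged F1 over the three classes; sampling
repeats with different training seeds feed a two-way fixed-effects ANOVA
(factors: model, subject) with post-hoc paired t-tests between models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedGroupKFold

from .models import CNN1DClassifier, CNN3DClassifier
from .preprocess import WindowedDataset
from .structures import flip_augment, to_block, to_flat, to_sbyd

logger = logging.getLogger(__name__)

CLASSES = ("left", "rest", "right")
MODEL_TAGS = ("cnn3d+block", "cnn3d+sbyd", "cnn1d+flat")


def macro_f1(y_true, y_pred) -> float:
    """Unweighted mean F1 over left/right/rest; an absent class scores 0."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty prediction set")
    if len(y_true) != len(y_pred):
        raise ValueError("prediction/label length mismatch")
    return float(
        f1_score(y_true, y_pred, labels=list(CLASSES), average="macro", zero_division=0)
    )


@dataclass
class SplitPlan:
    scheme: str
    folds: list  # (name, train_idx, test_idx)


def make_splits(dataset: WindowedDataset, scheme: str) -> SplitPlan:
    """Deterministic train/test folds for the requested scheme."""
    subjects = np.unique(dataset.subject_ids)
    if scheme == "subject_independent":
        if len(subjects) < 2:
            raise ValueError("subject-independent evaluation needs >= 2 subjects")
        folds = []
        for sub in subjects:
            test = np.flatnonzero(dataset.subject_ids == sub)
            train = np.flatnonzero(dataset.subject_ids != sub)
            folds.append((f"subject{sub}", train, test))
        return SplitPlan(scheme, folds)
    if scheme == "mixed":
        # hold out each subject's last collection session
        test_mask = np.zeros(len(dataset), dtype=bool)
        for sub in subjects:
            runs = dataset.run_ids[dataset.subject_ids == sub]
            last = runs.max()
            test_mask |= (dataset.subject_ids == sub) & (dataset.run_ids == last)
        folds = [("heldout_session", np.flatnonzero(~test_mask), np.flatnonzero(test_mask))]
        return SplitPlan(scheme, folds)
    raise ValueError(f"unknown scheme {scheme!r}")


def assert_no_leakage(dataset: WindowedDataset, train_idx, test_idx) -> None:
    """Hard guard: no (subject, run) session appears on both sides."""
    train_sessions = set(dataset.session_keys[train_idx])
    test_sessions = set(dataset.session_keys[test_idx])
    common = train_sessions & test_sessions
    if common:
        raise AssertionError(f"session leakage between train and test: {common}")


def _structure_views(dataset: WindowedDataset, tags=MODEL_TAGS):
    views = {}
    if any(t.endswith("block") for t in tags):
        views["block"] = to_block(dataset)
    if any(t.endswith("flat") for t in tags):
        views["flat"] = to_flat(dataset)
    if any(t.endswith("sbyd") for t in tags):
        views["sbyd"] = to_sbyd(dataset)
    return views


def _make_model(tag: str, seed: int, n_epochs: int | None, overrides: dict | None = None):
    params = dict(overrides or {})
    if n_epochs is not None:
        params.setdefault("n_epochs", n_epochs)
    params["seed"] = seed
    if tag.startswith("cnn3d"):
        return CNN3DClassifier(**params)
    if tag.startswith("cnn1d"):
        return CNN1DClassifier(**params)
    raise ValueError(f"unknown model tag {tag!r}")


def fit_and_score(
    tag: str,
    views: dict,
    dataset: WindowedDataset,
    train_idx,
    test_idx,
    seed: int,
    n_epochs: int | None = None,
    augment: bool = True,
    overrides: dict | None = None,
) -> dict:
    """Train one model on one fold; returns per-subject macro F1 scores."""
    assert_no_leakage(dataset, train_idx, test_idx)
    structure = tag.split("+")[1]
    view = views[structure]
    tr = view.subset(train_idx, split="train")
    te = view.subset(test_idx, split="test")
    if structure == "block" and augment:
        tr = flip_augment(tr)
    clf = _make_model(tag, seed, n_epochs, overrides)
    clf.fit(tr.values, tr.labels)
    pred = clf.predict(te.values)
    scores = {}
    for sub in np.unique(te.subject_ids):
        m = te.subject_ids == sub
        scores[int(sub)] = macro_f1(te.labels[m], pred[m])
    return scores


def run_comparison(
    dataset: WindowedDataset,
    scheme: str,
    n_repeats: int = 10,
    base_seed: int = 0,
    n_epochs: int | None = None,
    tags=MODEL_TAGS,
) -> pd.DataFrame:
    """Train every model x fold x repeat; rows of (model, subject, seed, F1)."""
    plan = make_splits(dataset, scheme)
    views = _structure_views(dataset, tags)
    rows = []
    for tag in tags:
        for rep in range(n_repeats):
            tag_offset = sum(ord(c) for c in tag)  # process-independent
            seed = (base_seed * 7919 + rep * 104729 + tag_offset) % (2**31 - 1)
            for fold_name, train_idx, test_idx in plan.folds:
                scores = fit_and_score(
                    tag, views, dataset, train_idx, test_idx, seed, n_epochs
                )
                for sub, score in scores.items():
                    rows.append(
                        {
                            "model": tag,
                            "scheme": scheme,
                            "fold": fold_name,
                            "subject": sub,
                            "repeat": rep,
                            "seed": seed,
                            "macro_f1": score,
                        }
                    )
                logger.info("%s %s rep %d fold %s done", tag, scheme, rep, fold_name)
    return pd.DataFrame(rows)


def summarise(results: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd macro F1 per (model, subject), Tables-style layout."""
    g = results.groupby(["model", "subject"])["macro_f1"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.pivot(index="model", columns="subject", values="mean")


# ---------------------------------------------------------------------------
# grid search


def grid_search(
    dataset: WindowedDataset,
    tag: str = "cnn3d+block",
    param_grid: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
    n_epochs: int | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Class-stratified, session-grouped K-fold cross-validated grid search.

    ``dataset`` must already exclude the held-out test sessions.  Folds are
    built so that no collection session's examples appear in both the
    training and validation side of a fold, while class proportions are
    approximately preserved.  Returns the best parameter dict (highest mean
    validation macro F1) and the full grid log.
    """
    sessions = dataset.session_keys
    n_sessions = len(set(sessions))
    if n_sessions < n_folds:
        raise ValueError(
            f"grid search needs >= {n_folds} sessions, got {n_sessions}"
        )
    if param_grid is None:
        param_grid = {}
    splitter = StratifiedGroupKFold(n_splits=n_folds)
    folds = list(splitter.split(dataset.values, dataset.labels, groups=sessions))
    views = _structure_views(dataset, (tag,))
    names = sorted(param_grid)
    rows = []
    for combo in product(*(param_grid[n] for n in names)) if names else [()]:
        overrides = dict(zip(names, combo))
        scores = []
        for train_idx, val_idx in folds:
            per_sub = fit_and_score(
                tag, views, dataset, train_idx, val_idx, seed, n_epochs,
                overrides=overrides,
            )
            scores.append(float(np.mean(list(per_sub.values()))))
        rows.append({**overrides, "mean_val_f1": float(np.mean(scores))})
        logger.info("grid %s -> %.3f", overrides, rows[-1]["mean_val_f1"])
    log = pd.DataFrame(rows)
    best = log.loc[log["mean_val_f1"].idxmax()]
    best_params = {n: best[n] for n in names}
    return best_params, log


# ---------------------------------------------------------------------------
# statistics


@dataclass
class StatsReport:
    shapiro: pd.DataFrame  # per (model, subject) cell: W, p
    anova: pd.DataFrame  # statsmodels ANOVA table (model, subject, residual)
    posthoc: pd.DataFrame  # per model pair: t, t_squared, p
    model_effect_f: float
    model_effect_p: float


def compare_stats(results: pd.DataFrame, posthoc_alpha: float = 0.05) -> StatsReport:
    """Shapiro-Wilk normality, two-way ANOVA, and post-hoc paired t-tests.

    The ANOVA is fixed-effects with factors model and subject (no
    interaction), i.e. model effects assessed while controlling for
    between-subject variation.  Requires a balanced design.  Post-hoc
    paired t-tests (pairing on subject x repeat) are computed when the
    model effect is significant; p-values are reported uncorrected.
    """
    from scipy import stats as sps
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    counts = results.groupby(["model", "subject"])["macro_f1"].count()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal repeats per (model, subject)")
    if counts.iloc[0] < 2:
        raise ValueError("need >= 2 repeats per cell for the ANOVA")

    shapiro_rows = []
    for (model, subject), grp in results.groupby(["model", "subject"]):
        x = grp["macro_f1"].to_numpy()
        if len(x) >= 3 and np.ptp(x) > 0:
            w, p = sps.shapiro(x)
        else:
            w, p = np.nan, np.nan
        shapiro_rows.append(
            {"model": model, "subject": subject, "W": w, "p": p}
        )
    shapiro = pd.DataFrame(shapiro_rows)

    df = results.copy()
    if df["macro_f1"].nunique() == 1:
        # degenerate: zero variance everywhere -> no model effect
        anova = pd.DataFrame()
        f_model, p_model = 0.0, 1.0
    else:
        fit = ols("macro_f1 ~ C(model) + C(subject)", data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        f_model = float(anova.loc["C(model)", "F"])
        p_model = float(anova.loc["C(model)", "PR(>F)"])

    posthoc_rows = []
    if p_model < posthoc_alpha:
        for a, b in combinations(sorted(df["model"].unique()), 2):
            key = ["subject", "repeat"]
            xa = df[df["model"] == a].sort_values(key)["macro_f1"].to_numpy()
            xb = df[df["model"] == b].sort_values(key)["macro_f1"].to_numpy()
            t, p = sps.ttest_rel(xa, xb)
            posthoc_rows.append(
                {
                    "model_a": a,
                    "model_b": b,
                    "t": float(t),
                    "t_squared": float(t) ** 2,
                    "p": float(p),
                }
            )
    posthoc = pd.DataFrame(posthoc_rows)
    return StatsReport(shapiro, anova, posthoc, f_model, p_model)
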