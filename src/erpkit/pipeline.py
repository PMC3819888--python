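"""End-to-end orchestration: cleaning, features, statistics, grouped CV.

The flow mirrors the full methodology: per subject-session, extended
Infomax ICA unmixes the 18-channel recording and EOG-correlated sources
are rejected; each retained source is decomposed by OEMD and reduced to
its task-relevant IMF (theta-dominant, peak 200-450 ms after target
onsets); the retained IMFs are back-projected to the 16 scalp channels;
epochs are cut -200..+800 ms around stimuli. Four per-channel feature
tables (P300 latency, P300 amplitude, RMS, theta power) are then
classified with subject-grouped stratified 5-fold cross-validation: in
every training fold a multiple kernel is evolved by GP (EMK-SVM), with
LDA and QDA fit on the same folds as baselines. Group statistics
(variance-ratio F, Welch t, Bonferroni-corrected multiple comparisons)
are reported per feature type.

Samples are subject-sessions by default; grouped folds guarantee that
no subject's sessions straddle a train/validation split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import emk, features, ica, oemd
from .emk import GPConfig
from .features import EpochSet, FeatureConfig
from .synth import Cohort, Recording

CLASSIFIERS = ("emk_svm", "lda", "qda")


@dataclass
class ICAConfig:
    mu: float = 0.01
    max_iter: int = 512
    tol: float = 1e-6
    block_size: int = 512
    artifact_threshold: float = 0.6
    remove_artifacts: bool = True
    n_eog: int = 2


@dataclass
class OEMDConfig:
    max_imfs: int = 7
    sd_threshold: float = 0.2
    max_sift_iter: int = 10
    window_ms: Tuple[float, float] = (200.0, 450.0)
    theta_band: Tuple[float, float] = (4.0, 8.0)
    select_imf: bool = True   # False keeps full sources (diagnostic mode)


@dataclass
class PipelineConfig:
    ica: ICAConfig = field(default_factory=ICAConfig)
    oemd: OEMDConfig = field(default_factory=OEMDConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    gp: GPConfig = field(default_factory=GPConfig)
    cv_folds: int = 5
    baselines: bool = True
    sample_unit: str = "subject-session"   # or "subject"
    seed: int = 0
    task: str = "0-back"
    pre_ms: float = 200.0
    post_ms: float = 800.0


@dataclass
class CVReport:
    accuracy: pd.DataFrame       # feature x classifier mean accuracy
    folds: pd.DataFrame          # per-fold accuracies
    kernels: pd.DataFrame        # best kernel per feature per fold
    statistics: pd.DataFrame     # F/t/p per feature type


def clean_recording(rec: Recording, ica_cfg: ICAConfig = ICAConfig(),
                    oemd_cfg: OEMDConfig = OEMDConfig(),
                    seed: int = 0, pre_ms: float = 200.0,
                    post_ms: float = 800.0) -> EpochSet:
    """ICA-OEMD cleaning of one recording, returning scalp-channel epochs."""
    if rec.events is None or len(rec.events) == 0:
        raise ValueError(f"recording {rec.subject}/{rec.session}: no events")
    targets = rec.target_onsets()
    if len(targets) == 0:
        raise ValueError(
            f"recording {rec.subject}/{rec.session}: no target events")
    eog_idx = [i for i, c in enumerate(rec.channel_names)
               if c.upper().startswith("EOG")][: ica_cfg.n_eog]
    scalp_idx = [i for i in range(len(rec.channel_names))
                 if i not in eog_idx]
    try:
        unmix = ica.fit_unmixing(
            rec.data, mu=ica_cfg.mu, max_iter=ica_cfg.max_iter,
            tol=ica_cfg.tol, seed=seed, block_size=ica_cfg.block_size)
        removed: List[int] = []
        if ica_cfg.remove_artifacts and eog_idx:
            report = ica.identify_artifact_components(
                unmix, rec.data[eog_idx], ica_cfg.artifact_threshold)
            removed = report.removed
        keep = [i for i in range(unmix.n_sources) if i not in removed]
        if not keep:
            raise ValueError("artifact rejection removed every source")
        S = unmix.sources.copy()
        if oemd_cfg.select_imf:
            for i in keep:
                imfset = oemd.decompose(
                    S[i], max_imfs=oemd_cfg.max_imfs,
                    sd_threshold=oemd_cfg.sd_threshold,
                    max_sift_iter=oemd_cfg.max_sift_iter)
                if imfset.M == 0:
                    continue
                sel = oemd.select_imf_of_interest(
                    imfset, rec.fs, targets,
                    window_ms=oemd_cfg.window_ms,
                    theta_band=oemd_cfg.theta_band, post_ms=post_ms)
                S[i] = imfset.recon_coeffs[sel.index] * imfset.imfs[sel.index]
        cleaned = unmix.A[:, keep] @ S[keep]
    except (ValueError, FloatingPointError) as err:
        raise type(err)(
            f"recording {rec.subject}/{rec.session}: {err}") from err
    return features.epoch_recording(
        cleaned[scalp_idx], rec.fs,
        rec.events["onset_sample"].to_numpy(),
        rec.events["type"].to_numpy(),
        [rec.channel_names[i] for i in scalp_idx],
        pre_ms=pre_ms, post_ms=post_ms)


def clean_cohort(cohort: Cohort, config: PipelineConfig
                 ) -> Dict[Tuple[str, int], EpochSet]:
    """Clean every recording of a cohort (seed threaded per recording)."""
    out = {}
    for i, rec in enumerate(cohort.recordings):
        out[(rec.subject, rec.session)] = clean_recording(
            rec, config.ica, config.oemd,
            seed=(config.seed + 7919 * i) % (2 ** 31),
            pre_ms=config.pre_ms, post_ms=config.post_ms)
    return out


def two_sample_stats(a: np.ndarray, b: np.ndarray
                     ) -> Tuple[float, float, float, float]:
    """Variance-ratio F test and Welch t test: (F, p_F, t, p_t)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero within-group variance")
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p_f = 2.0 * min(stats.f.sf(F, dfa, dfb), stats.f.cdf(F, dfa, dfb))
    t, p_t = stats.ttest_ind(a, b, equal_var=False)
    return float(F), float(min(p_f, 1.0)), float(t), float(p_t)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p value: min(1, m * p)."""
    return min(1.0, m * p)


def group_feature_tests(tables: Dict[str, pd.DataFrame],
                        grouping: str = "label",
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature group statistics (two-group and task x group layouts).

    Per feature type, channels are summarized by the channel with the
    largest |t| between the two groups; that channel's values feed the
    F/t tests. If more than one task is present, a one-way F across the
    task x group cells plus Bonferroni-adjusted pairwise comparisons is
    reported as well.
    """
    rows = []
    for ft, table in tables.items():
        groups = sorted(table[grouping].unique())
        if len(groups) < 2:
            raise ValueError("need two groups for statistics")
        channels = [c for c in table.columns
                    if c not in ("subject", "session", "task", grouping)]
        tasks = sorted(table["task"].unique())
        for task in tasks:
            sub = table[table["task"] == task]
            best_t, best_ch = 0.0, channels[0]
            for ch in channels:
                a = sub.loc[sub[grouping] == groups[0], ch].to_numpy()
                b = sub.loc[sub[grouping] == groups[1], ch].to_numpy()
                t = stats.ttest_ind(a, b, equal_var=False).statistic
                if np.isfinite(t) and abs(t) >= abs(best_t):
                    best_t, best_ch = t, ch
            a = sub.loc[sub[grouping] == groups[0], best_ch].to_numpy()
            b = sub.loc[sub[grouping] == groups[1], best_ch].to_numpy()
            F, p_f, t, p_t = two_sample_stats(a, b)
            rows.append({"feature": ft, "task": task, "channel": best_ch,
                         "F": F, "p_F": p_f, "t": t, "p_t": p_t,
                         "comparison": f"{groups[0]} vs {groups[1]}",
                         "significant_pairs": ""})
        if len(tasks) >= 2:
            ch = rows[-1]["channel"]
            cells = {(task, g): table.loc[(table["task"] == task) &
                                          (table[grouping] == g), ch]
                     .to_numpy()
                     for task in tasks for g in groups}
            keys = list(cells)
            F_all, p_all = stats.f_oneway(*[cells[k] for k in keys])
            m = len(keys) * (len(keys) - 1) // 2
            sig = []
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    p = stats.ttest_ind(cells[keys[i]], cells[keys[j]],
                                        equal_var=False).pvalue
                    if bonferroni(float(p), m) < alpha:
                        sig.append(f"{keys[i][0]}({keys[i][1]})"
                                   f"-{keys[j][0]}({keys[j][1]})")
            rows.append({"feature": ft, "task": "all", "channel": ch,
                         "F": float(F_all), "p_F": float(p_all),
                         "t": np.nan, "p_t": np.nan,
                         "comparison": "task x group",
                         "significant_pairs": "; ".join(sig)})
    return pd.DataFrame(rows)


def aggregate_to_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Average feature columns over sessions, one row per subject."""
    meta = ["subject", "task", "label"]
    channels = [c for c in table.columns
                if c not in meta and c != "session"]
    agg = table.groupby(meta, as_index=False)[channels].mean()
    agg.insert(1, "session", -1)
    return agg


def _fold_indices(table: pd.DataFrame, config: PipelineConfig):
    y = table["label"].to_numpy()
    groups = table["subject"].to_numpy()
    # grouped folds hold out whole subjects: feasibility is limited by
    # the number of subjects in the smallest class
    subj_per_class = table.groupby("label")["subject"].nunique()
    if config.cv_folds > subj_per_class.min():
        raise ValueError(
            f"{config.cv_folds}-fold grouped CV infeasible: smallest "
            f"class has {subj_per_class.min()} subjects; use at most "
            f"{subj_per_class.min()} folds")
    sgk = StratifiedGroupKFold(n_splits=config.cv_folds, shuffle=True,
                               random_state=config.seed % (2 ** 31))
    return list(sgk.split(table, y, groups=groups))


def _fit_qda(Xtr: np.ndarray, ytr: np.ndarray):
    """QDA with PCA reduction when a class has fewer samples than features."""
    from sklearn.decomposition import PCA
    from sklearn.pipeline import make_pipeline

    min_class = int(pd.Series(ytr).value_counts().min())
    qda = QuadraticDiscriminantAnalysis(reg_param=0.1)
    if min_class <= Xtr.shape[1]:
        return make_pipeline(PCA(n_components=max(min_class - 1, 1)),
                             qda).fit(Xtr, ytr)
    return qda.fit(Xtr, ytr)


def run_cv(tables: Dict[str, pd.DataFrame],
           config: PipelineConfig) -> CVReport:
    """Grouped stratified CV of all four feature tables, three classifiers."""
    fold_rows, kernel_rows = [], []
    for ft, table in tables.items():
        if config.sample_unit == "subject":
            table = aggregate_to_subject(table)
        channels = [c for c in table.columns
                    if c not in ("subject", "session", "task", "label")]
        X_all = table[channels].to_numpy(dtype=float)
        y_all = table["label"].to_numpy()
        splits = _fold_indices(table, config)
        for k, (tr, te) in enumerate(splits):
            tr_subj = set(table["subject"].to_numpy()[tr])
            te_subj = set(table["subject"].to_numpy()[te])
            assert not tr_subj & te_subj, "subject leaked across folds"
            # standardize on the training fold, then scale by 1/sqrt(d) so
            # pairwise squared distances are O(1): the base kernels have
            # fixed width/offset and assume distances on that scale
            scaler = StandardScaler().fit(X_all[tr])
            root_d = np.sqrt(X_all.shape[1])
            Xtr = scaler.transform(X_all[tr]) / root_d
            Xte = scaler.transform(X_all[te]) / root_d
            ytr, yte = y_all[tr], y_all[te]

            gp_cfg = dataclasses.replace(
                config.gp, seed=(config.gp.seed + 104729 * k) % (2 ** 31))
            evo = emk.evolve(Xtr, ytr, gp_cfg,
                             groups=table["subject"].to_numpy()[tr])
            G_tr, _ = emk.gram_matrix(evo.best_tree, Xtr)
            kp, kr = emk.base_kernels(Xte, Xtr)
            try:
                clf = SVC(C=gp_cfg.svm_c, kernel="precomputed",
                          max_iter=20000).fit(G_tr, ytr)
                acc = float(np.mean(
                    clf.predict(np.asarray(evo.best_tree.evaluate(kp, kr),
                                           dtype=float)) == yte))
            except ValueError:
                acc = 0.0
            fold_rows.append({"feature": ft, "classifier": "emk_svm",
                              "fold": k, "accuracy": acc})
            kernel_rows.append({"feature": ft, "fold": k,
                                "expression": evo.best_tree.to_string(),
                                "generation": evo.best_generation,
                                "train_fitness": evo.best_fitness})
            if config.baselines:
                lda = LinearDiscriminantAnalysis().fit(Xtr, ytr)
                qda = _fit_qda(Xtr, ytr)
                for name, model in (("lda", lda), ("qda", qda)):
                    fold_rows.append({
                        "feature": ft, "classifier": name, "fold": k,
                        "accuracy": float(np.mean(
                            model.predict(Xte) == yte))})
    folds = pd.DataFrame(fold_rows)
    accuracy = (folds.pivot_table(index="feature", columns="classifier",
                                  values="accuracy", aggfunc="mean")
                .reindex(list(tables)))
    return CVReport(accuracy=accuracy, folds=folds,
                    kernels=pd.DataFrame(kernel_rows),
                    statistics=pd.DataFrame())


def run_pipeline(cohort: Cohort, config: PipelineConfig) -> CVReport:
    """Cohort -> cleaning -> feature tables -> statistics -> grouped CV."""
    epochsets = clean_cohort(cohort, config)
    tables = features.extract_feature_table(
        epochsets, cohort.labels, config.features, task=config.task)
    report = run_cv(tables, config)
    report.statistics = group_feature_tests(tables)
    return report


def write_report(report: CVReport, out_dir, config: Optional[PipelineConfig]
                 = None) -> Dict[str, str]:
    """Write delimited result tables plus a reproducibility manifest."""
    import json
    import pathlib
    import sys

    out = pathlib.Path(out_dir)
    if out.exists() and not out.is_dir():
        raise ValueError(f"{out} exists and is not a directory")
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("accuracy", report.accuracy.reset_index()),
                     ("folds", report.folds),
                     ("kernels", report.kernels),
                     ("statistics", report.statistics)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    import numpy, scipy, sklearn, pywt  # noqa: E401
    from . import __version__
    manifest = {
        "erpkit": __version__,
        "python": sys.version.split()[0],
        "numpy": numpy.__version__, "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__, "pywavelets": pywt.__version__,
        "config": dataclasses.asdict(config) if config else None,
    }
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    paths["manifest"] = str(p)
    return paths
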