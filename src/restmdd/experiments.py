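"""Canned validation experiments for the pipeline.

These functions bundle the package's standard self-checks at desk scale:
structural contracts (feature count, split sizes, segmentation), analytic
feature values, oracle comparisons, null-cohort calibration, recovery of the
injected group effect, and artifact-removal efficacy. They are used by the
acceptance script and the test suite.

Desk-scale study conditions: 140 subjects (70 MDD / 70 healthy), 200 Hz,
five 20 s resting periods (100 s of rest per subject; the clinical protocol
also includes brief photic and hyperventilation phases, unused by the
features), subject-wise 100/40 split, 10-fold CV. Model-evaluation cohorts
are simulated artifact-free and preprocessed with the ICA stage disabled —
with no artifacts to remove, this isolates the classification question from
component-removal variance; artifact handling is validated separately by
:func:`artifact_restoration`.
"""
from __future__ import annotations

import time

import numpy as np
import scipy.signal

from .cohort import (ArtifactSpec, SpectralProfile, SubjectProfile,
                     make_default_protocol, synth_cohort, synth_recording,
                     inject_artifacts)
from .features import build_feature_table, features_for_subject
from .modeling import (mi_rank_features, run_experiment, select_top_k,
                       stratified_subject_split)
from .preprocess import extract_resting_periods, preprocess_recording

#: Protocol used by the canned experiments: 5 x 20 s resting periods plus
#: brief photic/hyperventilation markers.
def desk_protocol():
    return make_default_protocol(total_resting_seconds=100.0,
                                 photic_seconds=2.0,
                                 hyperventilation_seconds=5.0)


def cohort_feature_table(seed: int, n_mdd: int = 70, n_healthy: int = 70,
                         spectral: SpectralProfile | None = None):
    """Simulate an artifact-free cohort and extract its feature table."""
    recs = synth_cohort(n_mdd=n_mdd, n_healthy=n_healthy, spectral=spectral,
                        artifacts=ArtifactSpec.none(),
                        protocol=desk_protocol(), seed=seed)
    vecs = []
    for rec in recs:
        clean, _ = preprocess_recording(rec, drop_policy="none")
        segments = extract_resting_periods(clean)
        vecs.append(features_for_subject(segments, group=rec.group))
    return build_feature_table(vecs)


def feature_extraction_check(seed: int) -> dict:
    """Feature-count contract and per-subject extraction time."""
    profile = SubjectProfile("timing", "HEALTHY", 35, "F", seed=seed)
    rec = synth_recording(profile, protocol=desk_protocol())
    segments = extract_resting_periods(rec)
    t0 = time.perf_counter()
    fv = features_for_subject(segments)
    elapsed = time.perf_counter() - t0
    n_segments = len(segments)
    return {"n_features": len(fv.values), "seconds_per_subject": elapsed,
            "n_segments": n_segments}


def split_check(table) -> dict:
    split = stratified_subject_split(table, test_size=40, seed=0)
    groups = table["group"]
    test_mdd = sum(groups[i] == "MDD" for i in split.test_ids)
    return {"n_train": len(split.train_ids), "n_test": len(split.test_ids),
            "test_mdd": test_mdd, "test_healthy": len(split.test_ids) - test_mdd}


def null_calibration(base_seed: int, n_cohorts: int = 3) -> dict:
    """Per-family test accuracy averaged over independent null cohorts.

    With the group effect switched off the cohort carries no diagnostic
    signal; a calibrated pipeline scores at chance (0.5) up to sampling
    noise on the 40-subject test sets.
    """
    spectral = SpectralProfile(group_effect={})
    family_accs: dict[str, list[float]] = {}
    for j in range(n_cohorts):
        seed = (base_seed + 7919 * (j + 1)) % (2**31)
        table = cohort_feature_table(seed, spectral=spectral)
        report = run_experiment(table, seed=seed)
        for cell in report.cells:
            family_accs.setdefault(f"{cell.family}/{cell.feature_set}",
                                   []).append(cell.accuracy)
    means = {k: float(np.mean(v)) for k, v in family_accs.items()}
    return {"per_cell_mean_accuracy": means,
            "max_abs_deviation": max(abs(v - 0.5) for v in means.values()),
            "n_cohorts": n_cohorts}


#: Alpha-band power features whose group distribution is shifted directly by
#: the injected alpha effect; used to audit MI feature retention.
def alpha_power_features(columns) -> list:
    return [c for c in columns
            if c.endswith(("_alpha_abs_power", "_alpha_rel_power",
                           "_alpha_rwe"))]


def effect_recovery(base_seed: int, n_runs: int = 5,
                    families=("SVM", "KNN", "NB"), k: int = 100) -> dict:
    """Repeated end-to-end recovery of the default injected group effect.

    For each seeded run: simulate a fresh 140-subject cohort with the
    default MDD effect (alpha x1.3, gamma x0.8), extract features, rank by
    mutual information on the training subjects, and evaluate the given
    families on the held-out 40. Reports each run's best test accuracy and
    the count of alpha power features retained in the MI top-100 (57 such
    features exist; chance level in a top-100 cut is ~10).
    """
    best_accs, alpha_counts = [], []
    for j in range(n_runs):
        seed = (base_seed + 104729 * (j + 1)) % (2**31)
        table = cohort_feature_table(seed)
        report = run_experiment(table, seed=seed, k=k, families=families)
        best_accs.append(report.best().accuracy)
        alpha = set(alpha_power_features(table.columns))
        alpha_counts.append(sum(f in alpha for f in report.selected_features))
    chance = round(100 * 57 / 570)
    return {
        "best_accuracies": best_accs,
        "runs_at_or_above_075": sum(a >= 0.75 for a in best_accs),
        "alpha_top100_counts": alpha_counts,
        "alpha_enrichment_frequency":
            float(np.mean([c >= 2 * chance for c in alpha_counts])),
        "n_runs": n_runs,
    }


def artifact_restoration(seed: int) -> dict:
    """Frontal delta and pooled 50 Hz power after cleaning an artifacted
    recording, relative to the identically preprocessed artifact-free
    recording (ratio 1 = perfect restoration)."""
    profile = SubjectProfile("restore", "HEALTHY", 35, "M", seed=seed)
    clean = synth_recording(profile, protocol=desk_protocol())
    dirty = inject_artifacts(clean, ArtifactSpec(), seed=seed + 1)
    ref, _ = preprocess_recording(clean, seed=seed)
    got, log = preprocess_recording(dirty, seed=seed)
    fp1 = clean.channel_index("Fp1")

    def welch_band(x, lo, hi):
        f, P = scipy.signal.welch(x, fs=clean.fs, nperseg=int(8 * clean.fs),
                                  axis=-1)
        return P[..., (f >= lo) & (f <= hi)].sum(axis=-1)

    delta_ratio = float(welch_band(got.data[fp1], 0.5, 4)
                        / welch_band(ref.data[fp1], 0.5, 4))
    p50_ratio = float(welch_band(got.data, 49, 51).mean()
                      / welch_band(ref.data, 49, 51).mean())
    return {"frontal_delta_ratio": delta_ratio, "p50_ratio": p50_ratio,
            "n_dropped_components": len(log["dropped"])}
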