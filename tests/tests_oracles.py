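"""Shared brute-force oracles and toy builders used by the test suite."""

from datetime import date, timedelta

import numpy as np

from snpflow.windows_io import VisitRecord


def concordance_auc(scores_i, scores_j):
    """O(n^2) probability-of-correct-ranking with ties counting one half."""
    si = np.asarray(scores_i)[:, None]
    sj = np.asarray(scores_j)[None, :]
    return float(((si > sj).sum() + 0.5 * (si == sj).sum()) / (si.size * sj.size))


def concordance_mauc(probs, labels):
    """Hand-Till mAUC by exhaustive pair counting."""
    present = np.unique(labels)
    vals = []
    for a, i in enumerate(present):
        for j in present[a + 1:]:
            a_ij = concordance_auc(probs[labels == i, i], probs[labels == j, i])
            a_ji = concordance_auc(probs[labels == j, j], probs[labels == i, j])
            vals.append(0.5 * (a_ij + a_ji))
    return float(np.mean(vals))


def toy_patient_visits(counts):
    """Patients P0, P1, ... with the given visit counts and drifting features."""
    visits = []
    for p, n in enumerate(counts):
        for t in range(n):
            visits.append(VisitRecord(
                f"P{p}", date(2012, 1, 1) + timedelta(days=160 * t),
                np.linspace(0, 1, 11) + 0.1 * t, min(2, t // 3)))
    return visits
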