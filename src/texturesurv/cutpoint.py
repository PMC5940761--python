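"""ROC-based dichotomization of continuous features.

Each texture feature is turned into a binary high-risk / low-risk variable by
the cutoff that maximizes Youden's index (sensitivity + specificity - 1)
against the recurrence label, scanning every observed value in both
directions.  A leave-one-out cross-validation variant re-derives the cutoff n
times on n-1 patients and takes the modal cutoff.

Conventions (the underlying method reports are silent on all of them):

* candidate thresholds are the observed feature values, not midpoints;
* the boundary value belongs to the "<=" side;
* Youden ties break toward higher specificity, then the larger cutoff,
  then the "<=" direction — fully deterministic reporting;
* modal-cutoff ties break toward the cutoff closest to the full-data one.

No multiple-testing correction is applied across features; treat the
resulting p-values as exploratory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

#: ``direction`` semantics: which side of the cutoff is the high-risk group.
LE, GT = "le", "gt"


def _validate(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D arrays of equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return values, labels


def roc_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, str]:
    """Oriented area under the ROC curve.

    Returns ``(auc, direction)`` with ``auc >= 0.5``; ``direction`` is the
    side of a cutoff that would be called high-risk (``"gt"`` when larger
    values associate with the positive label, ``"le"`` otherwise).  Ties count
    one half, i.e. the AUC equals the tie-corrected Mann-Whitney
    ``U/(n1*n2)``.
    """
    values, labels = _validate(values, labels)
    auc = float(roc_auc_score(labels, values))
    if auc >= 0.5:
        return auc, GT
    return 1.0 - auc, LE


@dataclass
class CutoffResult:
    """An ROC-optimal dichotomization of one feature."""

    feature_id: str
    auc: float
    cutoff: float
    direction: str  # "le": value <= cutoff is high-risk; "gt": value > cutoff is
    sensitivity: float
    specificity: float
    degenerate: bool = False

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def describe(self, decimals: int = 6) -> str:
        op = "<=" if self.direction == LE else ">"
        return f"{self.feature_id} {op} {round(self.cutoff, decimals)}"


def youden_cutoff(values: np.ndarray, labels: np.ndarray,
                  feature_id: str = "feature") -> CutoffResult:
    """Cutoff maximizing sensitivity + specificity, scanning observed values.

    Both directions are scanned.  For direction ``"le"`` a patient is called
    high-risk when ``value <= cutoff``; sensitivity is the fraction of
    positive-label (recurrence) patients called high-risk and specificity the
    fraction of negative-label patients called low-risk.  When no split beats
    chance (e.g. all values equal) the result carries ``degenerate=True``.
    """
    values, labels = _validate(values, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    cands = np.unique(values)

    # Counts of (value <= c) per class, for every candidate c at once.
    pos_sorted = np.sort(values[labels])
    neg_sorted = np.sort(values[~labels])
    pos_le = np.searchsorted(pos_sorted, cands, side="right")
    neg_le = np.searchsorted(neg_sorted, cands, side="right")

    # Integer-count arithmetic on both sides keeps ties exactly reproducible.
    sens_le = pos_le / n_pos
    spec_le = (n_neg - neg_le) / n_neg
    sens_gt = (n_pos - pos_le) / n_pos
    spec_gt = neg_le / n_neg

    best = None  # (youden, specificity, cutoff, dir_pref) maximized lexicographically
    for direction, sens, spec in ((LE, sens_le, spec_le), (GT, sens_gt, spec_gt)):
        j = sens + spec - 1.0
        pref = 1.0 if direction == LE else 0.0
        order = np.lexsort((np.full(cands.size, pref), cands, spec, j))
        k = order[-1]
        cand = (float(j[k]), float(spec[k]), float(cands[k]), pref,
                direction, float(sens[k]))
        if best is None or cand[:4] > best[:4]:
            best = cand

    j_max, spec_best, cutoff, _, direction, sens_best = best
    auc, _ = roc_auc(values, labels)
    return CutoffResult(
        feature_id=feature_id, auc=auc, cutoff=cutoff, direction=direction,
        sensitivity=sens_best, specificity=spec_best,
        degenerate=bool(j_max <= 0.0),
    )


def dichotomize(values: np.ndarray, cutoff: float, direction: str) -> np.ndarray:
    """Boolean high-risk labels; the boundary value belongs to the "<=" side."""
    values = np.asarray(values, dtype=float)
    if direction == LE:
        return values <= cutoff
    if direction == GT:
        return values > cutoff
    raise ValueError(f"direction must be {LE!r} or {GT!r}, got {direction!r}")


@dataclass
class LoocvCutoff:
    """Leave-one-out cross-validated cutoff selection.

    ``fold_assignments[i]`` is the held-out high-risk call for patient i made
    by the cutoff fitted on the other n-1 patients; ``modal_cutoff`` is the
    per-fold cutoff selected most frequently.
    """

    per_fold_cutoffs: np.ndarray
    per_fold_directions: list[str]
    modal_cutoff: float
    modal_direction: str
    fold_assignments: np.ndarray
    skipped_folds: list[int] = field(default_factory=list)


def loocv_cutoff(values: np.ndarray, labels: np.ndarray,
                 feature_id: str = "feature",
                 round_decimals: int | None = None) -> LoocvCutoff:
    """Leave-one-out Youden cutoffs plus the modal cutoff.

    Folds whose training half contains a single class are skipped (and
    listed in ``skipped_folds``); the held-out patient is then assigned by
    the full-data cutoff.  Continuous cutoffs rarely repeat exactly, so
    ``round_decimals`` optionally rounds per-fold cutoffs before the mode is
    taken; modal ties break toward the cutoff closest to the full-data
    Youden cutoff.
    """
    values, labels = _validate(values, labels)
    n = values.size
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 patients")
    full = youden_cutoff(values, labels, feature_id=feature_id)

    cutoffs = np.full(n, np.nan)
    directions: list[str] = [""] * n
    assignments = np.zeros(n, dtype=bool)
    skipped: list[int] = []
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        keep[i] = False
        lab = labels[keep]
        if lab.all() or not lab.any():
            skipped.append(i)
            assignments[i] = dichotomize(values[i:i + 1], full.cutoff, full.direction)[0]
        else:
            fold = youden_cutoff(values[keep], lab, feature_id=feature_id)
            cutoffs[i] = fold.cutoff
            directions[i] = fold.direction
            assignments[i] = dichotomize(values[i:i + 1], fold.cutoff, fold.direction)[0]
        keep[i] = True

    valid = ~np.isnan(cutoffs)
    if not valid.any():
        raise ValueError("all leave-one-out folds were degenerate")
    fold_cuts = cutoffs[valid]
    keys = np.round(fold_cuts, round_decimals) if round_decimals is not None else fold_cuts
    uniq, counts = np.unique(keys, return_counts=True)
    top = uniq[counts == counts.max()]
    modal = float(top[np.argmin(np.abs(top - full.cutoff))])
    # Direction reported with the modal cutoff: majority among its folds.
    dirs = [d for d, k in zip(np.asarray(directions)[valid], keys) if k == modal]
    modal_dir = max(set(dirs), key=dirs.count) if dirs else full.direction

    return LoocvCutoff(
        per_fold_cutoffs=fold_cuts,
        per_fold_directions=[d for d in np.asarray(directions)[valid]],
        modal_cutoff=modal,
        modal_direction=modal_dir,
        fold_assignments=assignments,
        skipped_folds=skipped,
    )
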