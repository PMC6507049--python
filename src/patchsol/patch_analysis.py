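"""Charged-patch segmentation and the solubility profile.

The surface is partitioned by the electrostatic potential at each dot into
positively-charged (> +25 mV), negatively-charged (< -25 mV) and non-charged
("HYD", within [-25, +25] mV) classes; connected components of the dot
neighbour graph restricted to each class are the patches.  The solubility
predictor is the area of the largest positive patch divided by a calibrated
threshold: a ratio above 1.0 predicts an insoluble protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .surface_mesh import DotSurface
from .structure_io import Structure

POS_CONTOUR_MV = 25.0
NEG_CONTOUR_MV = -25.0

POS, NEG, HYD = "POS", "NEG", "HYD"


@dataclass
class Patch:
    sign_class: str                  # POS | NEG | HYD
    dot_indices: np.ndarray          # sorted int indices into the surface
    area: float                      # Å**2
    member_residues: frozenset[tuple[str, int]] = frozenset()


@dataclass
class PatchSet:
    patches: list[Patch]
    posQmax: float
    negQmax: float
    hydmax: float
    total_area: float

    def largest(self, sign_class: str) -> Patch | None:
        cands = [p for p in self.patches if p.sign_class == sign_class]
        return max(cands, key=lambda p: p.area) if cands else None


@dataclass
class SolubilityProfile:
    posQmax: float
    threshold: float
    ratio: float
    prediction: str                  # "soluble" | "insoluble"
    hydmax: float = 0.0
    # supplementary (positive, non-charged) pair — reported, no own threshold
    @property
    def supplementary(self) -> tuple[float, float]:
        return (self.ratio, self.hydmax)


def classify_dots(potentials: np.ndarray,
                  pos_mv: float = POS_CONTOUR_MV,
                  neg_mv: float = NEG_CONTOUR_MV) -> np.ndarray:
    """Per-dot sign class: +1 above +contour, -1 below -contour, 0 between.

    Strict inequalities on both contours; the closed interval is the
    non-charged class.
    """
    lab = np.zeros(len(potentials), dtype=np.int8)
    lab[potentials > pos_mv] = 1
    lab[potentials < neg_mv] = -1
    return lab


def segment_patches(
    surface: DotSurface,
    potentials: np.ndarray,
    structure: Structure | None = None,
    pos_mv: float = POS_CONTOUR_MV,
    neg_mv: float = NEG_CONTOUR_MV,
) -> PatchSet:
    """Connected same-sign components of the dot graph.

    Requires :func:`surface_mesh.link_neighbours` to have been run.  If a
    structure is supplied, each patch records the residues parenting at
    least one member dot (used by the mutation screen).
    """
    if surface.adjacency is None:
        raise ValueError("surface has no neighbour graph; call link_neighbours first")
    potentials = np.asarray(potentials, dtype=float)
    if len(potentials) != surface.n_dots:
        raise ValueError("potential field not aligned with surface dots")

    labels = classify_dots(potentials, pos_mv, neg_mv)
    adj = surface.adjacency.tocoo()
    # drop edges that cross sign classes, then one global component pass
    same = labels[adj.row] == labels[adj.col]
    from scipy import sparse

    sub = sparse.coo_matrix(
        (adj.data[same], (adj.row[same], adj.col[same])), shape=adj.shape
    ).tocsr()
    n_comp, comp = connected_components(sub, directed=False)

    atom_residue = None
    if structure is not None:
        atom_residue = [(a.chain_id, a.residue_seq) for a in structure.atoms]

    patches: list[Patch] = []
    order = np.argsort(comp, kind="stable")
    comp_sorted = comp[order]
    boundaries = np.flatnonzero(np.diff(comp_sorted)) + 1
    groups = np.split(order, boundaries)
    for g in groups:
        cls = {1: POS, -1: NEG, 0: HYD}[int(labels[g[0]])]
        area = float(surface.areas[g].sum())
        members: frozenset[tuple[str, int]] = frozenset()
        if atom_residue is not None:
            members = frozenset(atom_residue[surface.parent_atom[i]] for i in g)
        patches.append(Patch(cls, np.sort(g), area, members))

    def _max(cls: str) -> float:
        areas = [p.area for p in patches if p.sign_class == cls]
        return max(areas) if areas else 0.0

    return PatchSet(
        patches=patches,
        posQmax=_max(POS),
        negQmax=_max(NEG),
        hydmax=_max(HYD),
        total_area=surface.total_area,
    )


def solubility_profile(patches: PatchSet, threshold: float) -> SolubilityProfile:
    """Ratio of the largest positive patch to the threshold; > 1.0 predicts
    insoluble (the boundary itself is called soluble)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ratio = patches.posQmax / threshold
    return SolubilityProfile(
        posQmax=patches.posQmax,
        threshold=threshold,
        ratio=ratio,
        prediction="insoluble" if ratio > 1.0 else "soluble",
        hydmax=patches.hydmax,
    )


# ---------------------------------------------------------------------------
# threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdCalibration:
    threshold: float
    balanced_accuracy: float
    data: list[tuple[float, str]] = field(default_factory=list, repr=False)


def calibrate_threshold(data: list[tuple[float, str]]) -> ThresholdCalibration:
    """Pick the patch-size cut that best separates soluble from insoluble.

    ``data`` is a list of (posQmax, label) with labels "soluble"/"insoluble".
    Candidates are midpoints of consecutive sorted unique sizes plus one
    candidate below the minimum and one above the maximum; the candidate
    maximising balanced accuracy wins, ties going to the smallest threshold.
    """
    labels = {lab for _, lab in data}
    if labels != {"soluble", "insoluble"}:
        raise ValueError("calibration needs both soluble and insoluble examples")
    sizes = np.array([x for x, _ in data], dtype=float)
    y_insol = np.array([lab == "insoluble" for _, lab in data])

    uniq = np.unique(sizes)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    best_t, best_acc = None, -1.0
    for t in candidates:
        pred_insol = sizes > t
        tpr = (pred_insol & y_insol).sum() / max(1, y_insol.sum())
        tnr = (~pred_insol & ~y_insol).sum() / max(1, (~y_insol).sum())
        acc = 0.5 * (tpr + tnr)
        if acc > best_acc + 1e-12:
            best_t, best_acc = float(t), float(acc)
    if best_acc <= 0.5 + 1e-12:
        warnings.warn(
            "labels are not separable by patch size better than chance "
            f"(balanced accuracy {best_acc:.2f})"
        )
    return ThresholdCalibration(best_t, best_acc, list(data))


class PatchSolubilityClassifier:
    """scikit-learn style wrapper around the threshold calibration.

    fit(X, y) with X of shape (n, 1) (or (n,)) holding largest-positive-patch
    areas and y in {"soluble", "insoluble"}; predict returns the same labels.
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "PatchSolubilityClassifier":
        if params:
            raise ValueError(f"unknown parameters: {sorted(params)}")
        return self

    def fit(self, X, y) -> "PatchSolubilityClassifier":
        X = np.asarray(X, dtype=float).reshape(-1)
        cal = calibrate_threshold(list(zip(X, list(y))))
        self.threshold_ = cal.threshold
        self.balanced_accuracy_ = cal.balanced_accuracy
        self.classes_ = np.array(["insoluble", "soluble"])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "threshold_"):
            raise ValueError("classifier is not fitted")
        X = np.asarray(X, dtype=float).reshape(-1)
        return np.where(X > self.threshold_, "insoluble", "soluble")

    def score(self, X, y) -> float:
        pred = self.predict(X)
        return float(np.mean(pred == np.asarray(y)))
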