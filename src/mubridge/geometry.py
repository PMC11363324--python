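"""Single-frame geometric detectors.

Hydrogen bonds between N/O heavy atoms, direct polar contacts, aromatic
ring centroids/normals, and face-to-face π–π stacking contacts. All
quantities are in Å and degrees, computed on one :class:`~mubridge.frames.Frame`
at a time; no periodic-boundary handling is performed (frames are assumed
pre-imaged).

Defaults: the heavy-atom hydrogen-bond window is ``[2.2, 3.0]`` Å, matching
the 2.5–3 Å donor–acceptor distances observed for the ligand–water–aspartate
bridges, with the lower bound guarding against steric clashes. The
donor–H···acceptor angle criterion (≥ 120°) is applied only when hydrogens
are present, so heavy-atom-only frames are scored on distance alone. π–π
stacking requires centroid distance ≤ 5.0 Å (rings farther apart than 5 Å
cannot form a robust stack), interplanar angle ≤ 30° and lateral offset
≤ 2.0 Å; angle and offset cutoffs follow common stacking conventions and
are configurable.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from mubridge.frames import Frame

__all__ = [
    "DEFAULT_HBOND_WINDOW",
    "DEFAULT_MIN_DHA_ANGLE",
    "PiPiCriteria",
    "HBond",
    "PiPiContact",
    "GeometryError",
    "detect_hbonds",
    "contact_direct",
    "ring_centroid_normal",
    "pipi_geometry",
    "detect_pipi",
]

DEFAULT_HBOND_WINDOW: tuple[float, float] = (2.2, 3.0)
DEFAULT_MIN_DHA_ANGLE: float = 120.0
_HBOND_ELEMENTS = frozenset({"N", "O"})
_COVALENT_H_CUTOFF = 1.25  # Å, H considered bonded to its heavy atom


class GeometryError(ValueError):
    """Degenerate geometry (e.g. collinear ring atoms)."""


@dataclasses.dataclass(frozen=True)
class HBond:
    """A heavy-atom hydrogen bond between atoms ``a`` and ``b``.

    ``a < b`` in frame atom-index order; in heavy-atom-only frames
    donor/acceptor assignment is undetermined so the pair is stored
    symmetrically. ``angle`` is the best D–H···A angle found, or None
    when no hydrogen is attached to either partner.
    """

    a: int
    b: int
    distance: float
    angle: float | None = None


@dataclasses.dataclass(frozen=True)
class PiPiCriteria:
    max_centroid_distance: float = 5.0
    max_interplanar_angle: float = 30.0
    max_lateral_offset: float = 2.0


@dataclasses.dataclass(frozen=True)
class PiPiContact:
    ring_a: str
    ring_b: str
    centroid_distance: float
    interplanar_angle: float
    lateral_offset: float


def _attached_hydrogens(frame: Frame) -> dict[int, np.ndarray]:
    """Map heavy-atom index -> (k, 3) coordinates of covalently bound H."""
    h_idx = [i for i, a in enumerate(frame.atoms) if a.element == "H"]
    if not h_idx:
        return {}
    heavy_idx = [i for i, a in enumerate(frame.atoms) if a.element in _HBOND_ELEMENTS]
    if not heavy_idx:
        return {}
    d = cdist(frame.coords[heavy_idx], frame.coords[h_idx])
    out: dict[int, list] = {}
    for hi_pos, hi in enumerate(heavy_idx):
        for hj_pos, hj in enumerate(h_idx):
            if (
                d[hi_pos, hj_pos] <= _COVALENT_H_CUTOFF
                and frame.atoms[hi].residue_key == frame.atoms[hj].residue_key
            ):
                out.setdefault(hi, []).append(frame.coords[hj])
    return {k: np.asarray(v, float) for k, v in out.items()}


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    """Donor–H···acceptor angle at the hydrogen, degrees (180 = linear)."""
    u = donor - hydrogen
    v = acceptor - hydrogen
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    frame: Frame,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
    min_angle: float = DEFAULT_MIN_DHA_ANGLE,
) -> list[HBond]:
    """All inter-residue N/O···N/O pairs within the distance window.

    When at least one partner carries a covalently bound hydrogen, the pair
    must additionally pass the D–H···A angle criterion (for some attached
    hydrogen); pairs where neither partner has hydrogens are accepted on
    distance alone. An empty frame yields an empty list.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"invalid distance window {window}: lower must be < upper")
    cand = [i for i, a in enumerate(frame.atoms) if a.element in _HBOND_ELEMENTS]
    if len(cand) < 2:
        return []
    xyz = frame.coords[cand]
    dmat = cdist(xyz, xyz)
    hmap = _attached_hydrogens(frame)
    bonds: list[HBond] = []
    for p in range(len(cand)):
        for q in range(p + 1, len(cand)):
            i, j = cand[p], cand[q]
            if frame.atoms[i].residue_key == frame.atoms[j].residue_key:
                continue
            dist = float(dmat[p, q])
            if not (lo <= dist <= hi):
                continue
            best_angle: float | None = None
            has_h = i in hmap or j in hmap
            if has_h:
                for donor, acceptor in ((i, j), (j, i)):
                    for hxyz in hmap.get(donor, ()):
                        ang = _dha_angle(
                            frame.coords[donor], hxyz, frame.coords[acceptor]
                        )
                        if best_angle is None or ang > best_angle:
                            best_angle = ang
                if best_angle is None or best_angle < min_angle:
                    continue
            bonds.append(HBond(a=min(i, j), b=max(i, j), distance=dist, angle=best_angle))
    return bonds


def contact_direct(
    frame: Frame,
    a: int,
    b_set: Sequence[int],
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
) -> bool:
    """True iff the min distance from atom ``a`` to ``b_set`` lies in the window."""
    if not b_set:
        raise ValueError("b_set must contain at least one atom index")
    d = np.linalg.norm(frame.coords[list(b_set)] - frame.coords[a], axis=1)
    dmin = float(d.min())
    lo, hi = window
    return lo <= dmin <= hi


def ring_centroid_normal(coords) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit plane normal of a (near-)planar ring.

    The normal is the eigenvector of the smallest eigenvalue of the
    coordinate covariance, with a fixed sign convention: positive z
    component, tie-broken by positive x then positive y.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise ValueError("ring requires at least 3 atoms with xyz coordinates")
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered
    evals, evecs = np.linalg.eigh(cov)
    # collinear atoms: two vanishing eigenvalues -> plane undefined
    scale = max(float(evals[-1]), 1e-30)
    if evals[1] <= 1e-10 * scale:
        raise GeometryError("ring atoms are collinear; plane normal is undefined")
    normal = evecs[:, 0]
    tol = 1e-9
    for comp in (2, 0, 1):
        if abs(normal[comp]) > tol:
            if normal[comp] < 0:
                normal = -normal
            break
    return centroid, normal / np.linalg.norm(normal)


def pipi_geometry(
    centroid_a: np.ndarray,
    normal_a: np.ndarray,
    centroid_b: np.ndarray,
    normal_b: np.ndarray,
) -> tuple[float, float, float]:
    """(centroid distance, interplanar angle in [0, 90]°, lateral offset).

    The lateral offset is the in-plane component of the centroid–centroid
    vector; the smaller of the two per-ring projections is reported, so a
    pair counts as stacked if either ring sits above the other's face.
    """
    dvec = np.asarray(centroid_b, float) - np.asarray(centroid_a, float)
    dist = float(np.linalg.norm(dvec))
    cosang = abs(float(np.dot(normal_a, normal_b)))
    angle = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
    offsets = []
    for n in (normal_a, normal_b):
        along = float(np.dot(dvec, n))
        offsets.append(float(np.linalg.norm(dvec - along * np.asarray(n, float))))
    return dist, angle, min(offsets)


def detect_pipi(
    frame: Frame,
    rings: Mapping[str, Sequence[int]],
    criteria: PiPiCriteria = PiPiCriteria(),
) -> list[PiPiContact]:
    """Face-to-face stacking contacts between every unordered pair of rings.

    ``rings`` maps a ring name to the frame atom indices of its members.
    A contact is reported iff centroid distance, interplanar angle and
    lateral offset are all within ``criteria``.
    """
    geoms = {}
    for name, idx in rings.items():
        idx = list(idx)
        if not idx or any(i >= len(frame.atoms) for i in idx):
            raise GeometryError(f"ring {name!r} refers to atoms missing from the frame")
        geoms[name] = ring_centroid_normal(frame.coords[idx])
    names = sorted(geoms)
    contacts: list[PiPiContact] = []
    for p in range(len(names)):
        for q in range(p + 1, len(names)):
            ca, na = geoms[names[p]]
            cb, nb = geoms[names[q]]
            dist, angle, offset = pipi_geometry(ca, na, cb, nb)
            if (
                dist <= criteria.max_centroid_distance
                and angle <= criteria.max_interplanar_angle
                and offset <= criteria.max_lateral_offset
            ):
                contacts.append(
                    PiPiContact(
                        ring_a=names[p],
                        ring_b=names[q],
                        centroid_distance=dist,
                        interplanar_angle=angle,
                        lateral_offset=offset,
                    )
                )
    return contacts
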