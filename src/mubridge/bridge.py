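"""Frame-wise classification of ligand -> sodium-site aspartate engagement.

Each frame is assigned exactly one label from ``{direct, water1, water2,
none}`` by an exclusion hierarchy: a frame counts as *direct* if the ligand
hydroxyl oxygen hydrogen-bonds a carboxylate oxygen; otherwise *water1* if
a single water bridges them; otherwise *water2* if two distinct consecutive
waters form a bridge; otherwise *none*. Bridges through three or more
waters are deliberately not scored. Frequencies are the fraction of frames
per class, summarised per simulation replicate with the across-replicate
mean and SEM, and compared between ligands with the Mann–Whitney U test.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from mubridge.frames import Frame, RoleMap
from mubridge.geometry import (
    DEFAULT_HBOND_WINDOW,
    PiPiCriteria,
    detect_hbonds,
    detect_pipi,
)

__all__ = [
    "CLASSES",
    "BridgeClassification",
    "FrequencyTable",
    "FractionSummary",
    "MannWhitneyResult",
    "classify_frame",
    "classify_frames",
    "bridge_frequencies",
    "compare_frequencies",
    "stacking_frequency",
    "hbond_frequency",
]

CLASSES: tuple[str, ...] = ("direct", "water1", "water2", "none")


@dataclasses.dataclass(frozen=True)
class BridgeClassification:
    """Per-frame label plus the hydrogen-bonded path that justifies it.

    ``path`` holds frame atom indices: ``(ligand O, carboxylate O)`` for
    direct, one or two intervening water oxygens for the bridged classes,
    and is empty for ``none``.
    """

    frame_index: int
    label: str
    path: tuple[int, ...]

    def __post_init__(self):
        expected = {"direct": 2, "water1": 3, "water2": 4, "none": 0}
        if self.label not in expected:
            raise ValueError(f"unknown class label {self.label!r}")
        if len(self.path) != expected[self.label]:
            raise ValueError(
                f"label {self.label!r} requires a path of length "
                f"{expected[self.label]}, got {len(self.path)}"
            )


def _in_window(d: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (d >= lo) & (d <= hi)


def classify_frame(
    frame: Frame,
    roles: RoleMap | None = None,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
) -> BridgeClassification:
    """Classify one frame with the direct > water1 > water2 > none hierarchy.

    The search runs over the hydrogen-bond graph restricted to {ligand
    hydroxyl O} ∪ {water O} ∪ {carboxylate O}; candidate atoms are visited
    in serial-number order so the reported path is deterministic. The
    direct contact uses the same distance window as the bridge links.
    """
    roles = roles or RoleMap.default()
    lig = roles.resolve_one(frame, "ligand_hydroxyl")
    ox = sorted(roles.require(frame, "carboxylate"), key=lambda i: frame.atoms[i].serial)
    waters = sorted(roles.resolve(frame, "water"), key=lambda i: frame.atoms[i].serial)

    ox_xyz = frame.coords[ox]
    lig_xyz = frame.coords[lig]

    d_lig_ox = np.linalg.norm(ox_xyz - lig_xyz, axis=1)
    hit = _in_window(d_lig_ox, window)
    if hit.any():
        o = ox[int(np.argmax(hit))]
        return BridgeClassification(frame.index, "direct", (lig, o))

    if waters:
        w_xyz = frame.coords[waters]
        d_lig_w = np.linalg.norm(w_xyz - lig_xyz, axis=1)
        lig_w = _in_window(d_lig_w, window)
        d_w_ox = cdist(w_xyz, ox_xyz)
        w_ox = _in_window(d_w_ox, window)

        for wi in range(len(waters)):
            if not lig_w[wi]:
                continue
            for oi in range(len(ox)):
                if w_ox[wi, oi]:
                    return BridgeClassification(
                        frame.index, "water1", (lig, waters[wi], ox[oi])
                    )

        d_ww = cdist(w_xyz, w_xyz)
        ww = _in_window(d_ww, window)
        for wi in range(len(waters)):
            if not lig_w[wi]:
                continue
            for wj in range(len(waters)):
                if wj == wi or not ww[wi, wj]:
                    continue
                for oi in range(len(ox)):
                    if w_ox[wj, oi]:
                        return BridgeClassification(
                            frame.index,
                            "water2",
                            (lig, waters[wi], waters[wj], ox[oi]),
                        )

    return BridgeClassification(frame.index, "none", ())


def classify_frames(
    frames: Iterable[Frame],
    roles: RoleMap | None = None,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
) -> list[BridgeClassification]:
    return [classify_frame(f, roles=roles, window=window) for f in frames]


@dataclasses.dataclass
class FrequencyTable:
    """Per-replicate class fractions plus across-replicate mean and SEM."""

    per_replicate: pd.DataFrame  # index: replicate, columns: CLASSES
    summary: pd.DataFrame  # index: CLASSES, columns: mean, sem

    def fraction(self, label: str) -> float:
        return float(self.summary.loc[label, "mean"])


def _sem(x: np.ndarray) -> float:
    # sample SD (ddof=1) over replicates / sqrt(R); undefined for R == 1
    if len(x) < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def bridge_frequencies(
    labels_by_replicate: Mapping[str, Sequence[str]],
) -> FrequencyTable:
    """Fractions of frames per class, per replicate, with mean ± SEM.

    Accepts either raw label sequences or sequences of
    :class:`BridgeClassification`.
    """
    if not labels_by_replicate:
        raise ValueError("at least one replicate is required")
    rows = {}
    for rep, labels in labels_by_replicate.items():
        labels = [
            lab.label if isinstance(lab, BridgeClassification) else lab for lab in labels
        ]
        if not labels:
            raise ValueError(f"replicate {rep!r} contains no frames")
        unknown = set(labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)} in replicate {rep!r}")
        n = len(labels)
        rows[rep] = {c: labels.count(c) / n for c in CLASSES}
    per_rep = pd.DataFrame.from_dict(rows, orient="index")[list(CLASSES)]
    summary = pd.DataFrame(
        {
            "mean": per_rep.mean(axis=0),
            "sem": [_sem(per_rep[c].to_numpy()) for c in CLASSES],
        }
    )
    return FrequencyTable(per_replicate=per_rep, summary=summary)


@dataclasses.dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float  # U of the first group
    p_value: float
    method: str  # "exact-enumeration" or "normal-approx"


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt + 0.5 * eq)


def compare_frequencies(
    freqs_a: Sequence[float],
    freqs_b: Sequence[float],
    max_exact: int = 8,
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test on per-replicate fractions.

    For groups of at most ``max_exact`` replicates the p-value is computed
    from the exact permutation distribution of U (all C(n+m, n) group
    assignments of the pooled values, so ties are handled exactly); larger
    groups use the tie-corrected normal approximation. Two-sided p is
    ``min(1, 2·min(P(U ≤ u), P(U ≥ u)))``.
    """
    a = np.asarray(freqs_a, float)
    b = np.asarray(freqs_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    u_obs = _u_statistic(a, b)
    if max(len(a), len(b)) <= max_exact:
        pooled = np.concatenate([a, b])
        n, total = len(a), len(pooled)
        us = []
        for pick in itertools.combinations(range(total), n):
            mask = np.zeros(total, bool)
            mask[list(pick)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        eps = 1e-12
        p_lo = float(np.mean(us <= u_obs + eps))
        p_hi = float(np.mean(us >= u_obs - eps))
        p = min(1.0, 2.0 * min(p_lo, p_hi))
        return MannWhitneyResult(u_obs, p, "exact-enumeration")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "normal-approx")


@dataclasses.dataclass
class FractionSummary:
    """Per-replicate fraction of frames satisfying a predicate, with mean ± SEM."""

    per_replicate: pd.Series
    mean: float
    sem: float


def _fraction_summary(fractions: Mapping[str, float]) -> FractionSummary:
    s = pd.Series(fractions, dtype=float)
    return FractionSummary(per_replicate=s, mean=float(s.mean()), sem=_sem(s.to_numpy()))


def stacking_frequency(
    frames_by_replicate: Mapping[str, Sequence[Frame]],
    rings: Mapping[str, Sequence[int]] | None = None,
    roles: RoleMap | None = None,
    criteria: PiPiCriteria = PiPiCriteria(),
) -> FractionSummary:
    """Fraction of frames with ≥1 qualifying π–π contact, per replicate.

    Rings default to the ligand phenyl vs. the 7.43 tyrosine phenol ring,
    resolved through the role map per frame; pass explicit atom-index
    ``rings`` to override.
    """
    roles = roles or RoleMap.default()
    fractions = {}
    for rep, frames in frames_by_replicate.items():
        if not frames:
            raise ValueError(f"replicate {rep!r} contains no frames")
        n_hit = 0
        for frame in frames:
            frame_rings = rings or {
                "ligand": roles.require(frame, "ligand_ring"),
                "tyrosine": roles.require(frame, "tyrosine_ring"),
            }
            if detect_pipi(frame, frame_rings, criteria):
                n_hit += 1
        fractions[rep] = n_hit / len(frames)
    return _fraction_summary(fractions)


def hbond_frequency(
    frames_by_replicate: Mapping[str, Sequence[Frame]],
    role_a: str,
    role_b: str,
    roles: RoleMap | None = None,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
    min_angle: float = 120.0,
) -> FractionSummary:
    """Fraction of frames with ≥1 hydrogen bond between two role atom sets.

    Used e.g. for the 7.43-tyrosine ↔ 2.60-glutamine hydrogen bond whose
    prevalence marks the alternative, arrestin-associated receptor
    conformation.
    """
    roles = roles or RoleMap.default()
    fractions = {}
    for rep, frames in frames_by_replicate.items():
        if not frames:
            raise ValueError(f"replicate {rep!r} contains no frames")
        n_hit = 0
        for frame in frames:
            set_a = set(roles.require(frame, role_a))
            set_b = set(roles.require(frame, role_b))
            bonds = detect_hbonds(frame, window=window, min_angle=min_angle)
            if any(
                (hb.a in set_a and hb.b in set_b) or (hb.a in set_b and hb.b in set_a)
                for hb in bonds
            ):
                n_hit += 1
        fractions[rep] = n_hit / len(frames)
    return _fraction_summary(fractions)


def classifications_to_frame(
    classifications: Sequence[BridgeClassification], frames: Sequence[Frame] | None = None
) -> pd.DataFrame:
    """Tidy per-frame classification table (frame_index, label, path serials)."""
    rows = []
    for c in classifications:
        if frames is not None:
            serials = "-".join(
                str(frames[c.frame_index].atoms[i].serial) for i in c.path
            )
        else:
            serials = "-".join(str(i) for i in c.path)
        rows.append({"frame_index": c.frame_index, "label": c.label, "path": serials})
    return pd.DataFrame(rows, columns=["frame_index", "label", "path"])
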