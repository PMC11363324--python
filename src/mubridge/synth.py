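"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the data the analysis stages consume:

- :func:`gen_bridge_frames` — structural snapshots with a designed
  ligand → aspartate bridge topology per frame (direct / one-water /
  two-water / none). Geometry is built in a local axis system with the
  carboxylate fixed at the origin, since classification depends only on
  relative geometry; only the atoms relevant to classification plus decoy
  waters are emitted. Coordinate jitter is re-sampled whenever it would
  flip the designed class, so the emitted truth labels always hold.
- :func:`gen_dose_response` — 4PL concentration-response data with
  additive Gaussian noise on the % response scale.
- :func:`gen_apex_timecourse` — a protein-intensity table with spatial
  reference samples (location-exclusive indicator proteins), receptor
  samples mixing locations over time, and a small set of truly changing
  proteins on a log2 effect profile among mean-zero nulls.
- :func:`gen_mpe_doses` — graded %MPE antinociception data from a
  two-parameter log-logistic with floor 0 / ceiling 100, clamped to
  [0, 100] at the subject level.

All generators take explicit integer seeds and no global random state, so
regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from mubridge.frames import Atom, Frame
from mubridge.geometry import DEFAULT_HBOND_WINDOW
from mubridge.pharm import four_pl, log_logistic_mpe

__all__ = [
    "FrameSpec",
    "CurveTruth",
    "ApexTruth",
    "MpeTruth",
    "FrameGeometryError",
    "gen_bridge_frames",
    "gen_dose_response",
    "gen_apex_timecourse",
    "gen_mpe_doses",
    "default_indicator_map",
]

_CLASSES = ("direct", "water1", "water2", "none")


class FrameGeometryError(RuntimeError):
    """No jittered placement realising the requested class could be found."""


@dataclasses.dataclass(frozen=True)
class FrameSpec:
    """Designed bridge topology for a frame ensemble.

    ``labels`` gives the class of every frame; ``jitter_sd`` is the
    isotropic Gaussian coordinate jitter (Å) applied to the mobile atoms
    (ligand hydroxyl O and waters).
    """

    labels: tuple[str, ...]
    jitter_sd: float = 0.0
    seed: int = 0
    replicate_id: str = "rep1"

    def __post_init__(self):
        if len(self.labels) < 1:
            raise ValueError("at least one frame is required")
        bad = set(self.labels) - set(_CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.labels)


# Base geometry (Å), local axis system: aspartate OD1 at the origin,
# OD2 along +x, the bridge path along +z. Mobile atoms are the ligand
# hydroxyl O and the waters; decoy waters sit > 4.5 Å off-path.
_ASP = {"CG": (1.1, 1.0, 0.0), "OD1": (0.0, 0.0, 0.0), "OD2": (2.2, 0.0, 0.0)}
_DECOYS = {"direct": [(6.0, 6.0, 3.0), (-6.0, 6.0, 3.0), (8.0, -8.0, 6.0)],
           "water1": [(6.0, 6.0, 3.0), (-6.0, 6.0, 3.0)],
           "water2": [(6.0, 6.0, 3.0)],
           "none": [(6.0, 6.0, 3.0), (-6.0, 6.0, 3.0), (8.0, -8.0, 6.0)]}
_LIG_O = {"direct": (0.0, 0.0, 2.7), "water1": (0.0, 0.0, 5.5),
          "water2": (0.0, 0.0, 8.25), "none": (0.0, 0.0, 5.5)}
_BRIDGE_WATERS = {"direct": [], "water1": [(0.0, 0.0, 2.75)],
                  "water2": [(0.0, 0.0, 5.5), (0.0, 0.0, 2.75)], "none": []}


def _classify_geometry(lig, ox, waters, window) -> str:
    """Label implied by raw geometry, mirroring the exclusion hierarchy."""
    lo, hi = window

    def inw(p, q):
        return lo <= float(np.linalg.norm(np.asarray(p) - np.asarray(q))) <= hi

    if any(inw(lig, o) for o in ox):
        return "direct"
    lig_w = [inw(lig, w) for w in waters]
    w_ox = [any(inw(w, o) for o in ox) for w in waters]
    if any(lw and wo for lw, wo in zip(lig_w, w_ox)):
        return "water1"
    for i, w1 in enumerate(waters):
        if not lig_w[i]:
            continue
        for j, w2 in enumerate(waters):
            if i != j and inw(w1, w2) and w_ox[j]:
                return "water2"
    return "none"


def _build_frame(label, lig_o, waters, index) -> Frame:
    atoms: list[Atom] = []
    coords: list = []
    serial = 1

    def add(name, resname, resid, chain, element, xyz):
        nonlocal serial
        atoms.append(Atom(serial, name, resname, resid, chain, element))
        coords.append(xyz)
        serial += 1

    for name, xyz in _ASP.items():
        add(name, "ASP", 114, "A", name[0], xyz)
    add("C1", "LIG", 1, "L", "C", tuple(np.asarray(lig_o) + (0.0, 0.0, 1.4)))
    add("O1", "LIG", 1, "L", "O", lig_o)
    for k, w in enumerate(waters):
        add("O", "HOH", 1001 + k, "W", "O", w)
    return Frame(atoms, np.asarray(coords, float), index=index)


def gen_bridge_frames(
    spec: FrameSpec,
    window: tuple[float, float] = DEFAULT_HBOND_WINDOW,
    max_tries: int = 200,
) -> tuple[list[Frame], list[str]]:
    """Frames realising ``spec.labels``, plus the emitted truth labels.

    Each frame's geometry is checked against the classification criteria
    after jitter; placements that would change the designed class are
    re-sampled (up to ``max_tries``), so downstream classification equals
    the truth labels by construction.
    """
    rng = np.random.default_rng(spec.seed)
    ox = list(_ASP[k] for k in ("OD1", "OD2"))
    frames: list[Frame] = []
    for idx, label in enumerate(spec.labels):
        base_lig = np.asarray(_LIG_O[label], float)
        base_waters = [np.asarray(w, float) for w in _BRIDGE_WATERS[label]] + [
            np.asarray(w, float) for w in _DECOYS[label]
        ]
        for _ in range(max_tries):
            lig = base_lig + rng.normal(0.0, spec.jitter_sd, 3)
            waters = [w + rng.normal(0.0, spec.jitter_sd, 3) for w in base_waters]
            if _classify_geometry(lig, ox, waters, window) == label:
                frames.append(_build_frame(label, tuple(lig), waters, idx))
                break
        else:
            raise FrameGeometryError(
                f"could not realise class {label!r} for frame {idx} with "
                f"jitter_sd={spec.jitter_sd} after {max_tries} attempts"
            )
    return frames, list(spec.labels)


@dataclasses.dataclass(frozen=True)
class CurveTruth:
    """Generating parameters for 4PL concentration-response data.

    ``noise_sd`` is in % response units (the same scale as the output);
    concentrations are log-spaced between ``10**log10_cmin`` and
    ``10**log10_cmax`` M.
    """

    pec50_true: float
    emax_true: float
    hill: float = 1.0
    baseline: float = 0.0
    noise_sd: float = 5.0
    n_conc: int = 8
    n_reps: int = 4
    log10_cmin: float = -10.0
    log10_cmax: float = -4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_conc < 4:
            raise ValueError("n_conc must be >= 4")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.emax_true < self.baseline:
            raise ValueError("emax_true must be >= baseline")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_dose_response(truth: CurveTruth) -> pd.DataFrame:
    """Concentration-response records (conc_M, response_pct, replicate)."""
    rng = np.random.default_rng(truth.seed)
    logc = np.linspace(truth.log10_cmin, truth.log10_cmax, truth.n_conc)
    rows = []
    for rep in range(1, truth.n_reps + 1):
        mean = four_pl(logc, truth.emax_true, truth.pec50_true, truth.hill,
                       truth.baseline)
        resp = mean + rng.normal(0.0, truth.noise_sd, truth.n_conc)
        for c, r in zip(10.0 ** logc, resp):
            rows.append({"conc_M": c, "response_pct": r, "replicate": rep})
    return pd.DataFrame(rows, columns=["conc_M", "response_pct", "replicate"])


def default_indicator_map(n_per_location: int = 10) -> dict[str, list[str]]:
    locs = ("plasma_membrane", "early_endosome", "lysosome")
    short = {"plasma_membrane": "PM", "early_endosome": "EE", "lysosome": "LYS"}
    return {
        loc: [f"IND_{short[loc]}_{k:02d}" for k in range(1, n_per_location + 1)]
        for loc in locs
    }


def _default_effect_profile() -> dict[float, float]:
    return {0.0: 0.0, 1.0: 0.75, 5.0: 1.0, 10.0: 0.75, 30.0: 0.0}


@dataclasses.dataclass(frozen=True)
class ApexTruth:
    """Generating structure for a receptor-APEX time-course matrix.

    ``effect_profile`` maps time (min) to the planted log2 fold change of
    the changing proteins; ``mixing_series`` maps time to the receptor's
    location-fraction vector (ordered as ``indicator_map``), each
    nonnegative and summing to 1. ``null_sd`` is the log2-scale
    measurement noise applied to every intensity.
    """

    n_proteins: int = 500
    n_changing: int = 3
    changing_ids: tuple[str, ...] | None = None
    effect_profile: Mapping[float, float] | None = None
    null_sd: float = 0.15
    indicator_map: Mapping[str, Sequence[str]] | None = None
    mixing_series: Mapping[float, Sequence[float]] | None = None
    n_replicates: int = 3
    seed: int = 0

    def resolved(self):
        effect = dict(self.effect_profile) if self.effect_profile else _default_effect_profile()
        imap = {k: list(v) for k, v in (self.indicator_map or default_indicator_map()).items()}
        times = sorted(effect)
        mixing = (
            {float(t): list(v) for t, v in self.mixing_series.items()}
            if self.mixing_series
            else {t: [1.0] + [0.0] * (len(imap) - 1) for t in times}
        )
        proteins = [f"PROT_{k:04d}" for k in range(1, self.n_proteins + 1)]
        changing = (
            list(self.changing_ids)
            if self.changing_ids is not None
            else proteins[: self.n_changing]
        )
        # validation
        flat = [p for ids in imap.values() for p in ids]
        if len(set(flat)) != len(flat):
            raise ValueError("indicator protein sets overlap across locations")
        if not set(changing) <= set(proteins):
            raise ValueError("changing_ids must be a subset of the protein set")
        if sorted(mixing) != times:
            raise ValueError("mixing_series times must match effect_profile times")
        for t, v in mixing.items():
            v = np.asarray(v, float)
            if len(v) != len(imap) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"mixing vector at t={t} must be nonnegative and sum to 1"
                )
        if self.null_sd < 0:
            raise ValueError("null_sd must be >= 0")
        return proteins, changing, effect, imap, mixing, times


def gen_apex_timecourse(truth: ApexTruth) -> pd.DataFrame:
    """Tidy intensity table: receptor time course + spatial references.

    Columns: ``protein_id, sample_type, location_or_time, replicate,
    intensity``. Reference samples carry the location name in
    ``location_or_time``; receptor samples carry the time point (min).
    """
    proteins, changing, effect, imap, mixing, times = truth.resolved()
    rng = np.random.default_rng(truth.seed)
    locs = list(imap)
    indicators = [p for ids in imap.values() for p in ids]

    base_log2 = {p: rng.normal(20.0, 2.0) for p in proteins}
    ind_log2 = {p: rng.normal(22.0, 1.0) for p in indicators}
    # location-exclusive profile: full intensity at home location,
    # ~0.8% background elsewhere
    profile = {
        p: np.array(
            [2.0 ** ind_log2[p] if p in set(imap[L]) else 2.0 ** (ind_log2[p] - 7.0)
             for L in locs]
        )
        for p in indicators
    }

    def noise():
        return 2.0 ** rng.normal(0.0, truth.null_sd)

    rows = []
    for L in locs:
        unit = np.array([1.0 if M == L else 0.0 for M in locs])
        for rep in range(1, truth.n_replicates + 1):
            for p in indicators:
                rows.append(
                    {"protein_id": p, "sample_type": f"reference:{L}",
                     "location_or_time": L, "replicate": rep,
                     "intensity": float(profile[p] @ unit) * noise()}
                )
            for p in proteins:
                rows.append(
                    {"protein_id": p, "sample_type": f"reference:{L}",
                     "location_or_time": L, "replicate": rep,
                     "intensity": 2.0 ** base_log2[p] * noise()}
                )
    for t in times:
        mix = np.asarray(mixing[t], float)
        for rep in range(1, truth.n_replicates + 1):
            for p in indicators:
                rows.append(
                    {"protein_id": p, "sample_type": "receptor",
                     "location_or_time": t, "replicate": rep,
                     "intensity": float(profile[p] @ mix) * noise()}
                )
            for p in proteins:
                shift = effect[t] if p in set(changing) else 0.0
                rows.append(
                    {"protein_id": p, "sample_type": "receptor",
                     "location_or_time": t, "replicate": rep,
                     "intensity": 2.0 ** (base_log2[p] + shift) * noise()}
                )
    return pd.DataFrame(
        rows,
        columns=["protein_id", "sample_type", "location_or_time", "replicate",
                 "intensity"],
    )


@dataclasses.dataclass(frozen=True)
class MpeTruth:
    """Generating parameters for graded %MPE antinociception data."""

    ed50_true: float
    slope: float = 2.0
    doses: tuple[float, ...] = (3.0, 10.0, 30.0)
    n_subjects: int = 8
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        d = np.asarray(self.doses, float)
        if len(d) < 1 or (d <= 0).any() or not np.all(np.diff(d) > 0):
            raise ValueError("doses must be strictly positive and increasing")
        if self.ed50_true <= 0:
            raise ValueError("ed50_true must be > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_mpe_doses(truth: MpeTruth) -> pd.DataFrame:
    """Subject-level %MPE records (dose_mg_kg, subject, mpe_pct), clamped to [0, 100]."""
    rng = np.random.default_rng(truth.seed)
    rows = []
    for dose in truth.doses:
        mean = float(log_logistic_mpe(dose, truth.ed50_true, truth.slope))
        vals = np.clip(mean + rng.normal(0.0, truth.noise_sd, truth.n_subjects),
                       0.0, 100.0)
        for s, v in enumerate(vals, start=1):
            rows.append({"dose_mg_kg": dose, "subject": s, "mpe_pct": float(v)})
    return pd.DataFrame(rows, columns=["dose_mg_kg", "subject", "mpe_pct"])
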