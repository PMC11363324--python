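import numpy as np
import pytest

from mubridge.frames import Atom, Frame


def make_frame(records, index=0):
    """Build a Frame from (name, resname, resid, chain, element, xyz) tuples."""
    atoms, coords = [], []
    for serial, (name, resname, resid, chain, element, xyz) in enumerate(records, 1):
        atoms.append(Atom(serial, name, resname, resid, chain, element))
        coords.append(xyz)
    return Frame(atoms, np.asarray(coords, float), index=index)


def water(i, xyz):
    return ("O", "HOH", 1000 + i, "W", "O", xyz)


def lig_hydroxyl(xyz):
    return ("O1", "LIG", 1, "L", "O", xyz)


def asp_carboxylate():
    """Sodium-site aspartate carboxylate oxygens: OD1 at origin, OD2 at +x."""
    return [
        ("OD1", "ASP", 114, "A", "O", (0.0, 0.0, 0.0)),
        ("OD2", "ASP", 114, "A", "O", (2.2, 0.0, 0.0)),
    ]


def hexagon(center=(0.0, 0.0, 0.0), normal=(0.0, 0.0, 1.0), radius=1.39):
    """Vertices of a regular hexagon (benzene-like ring) in a given plane."""
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    # build an orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    angles = np.arange(6) * np.pi / 3
    return [
        np.asarray(center, float) + radius * (np.cos(a) * u + np.sin(a) * v)
        for a in angles
    ]


def ring_frame(center_b, normal_b=(0, 0, 1), center_a=(0, 0, 0), normal_a=(0, 0, 1)):
    """Frame with a ligand phenyl (ring A) and a tyrosine phenol ring (ring B)."""
    lig_names = ["C2", "C3", "C4", "C5", "C6", "C7"]
    tyr_names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    records = [
        (n, "LIG", 1, "L", "C", xyz)
        for n, xyz in zip(lig_names, hexagon(center_a, normal_a))
    ] + [
        (n, "TYR", 326, "A", "C", xyz)
        for n, xyz in zip(tyr_names, hexagon(center_b, normal_b))
    ]
    return make_frame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
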