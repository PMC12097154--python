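"""Per-residue solvent accessibility, depth and disorder from structures.

Works on predicted models (PDB or mmCIF; per-residue confidence read
from the B-factor column). Accessible surface area is computed with the
Shrake-Rupley sphere-sampling method and normalized to relative solvent
accessibility (RSA) by the Tien et al. theoretical maximum ASA per amino
acid. Residue depth is approximated as the distance from each atom to
the nearest solvent-accessible sphere point minus the probe radius, so
surface atoms score about one van der Waals radius and deeply buried
atoms their true distance from solvent — sufficient for the shallow/deep
dichotomy at the 3.6 A threshold used downstream. Disorder around a
residue is the window mean of RSA (clamped to [0, 1]), the
surface-accessibility form of a structure-based disorder score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = ["StructureModel", "read_structure", "compute_surface",
           "compute_depth", "residue_profile", "accessible_lysines",
           "window_disorder", "compare_groups", "classify_lis", "LISRecord",
           "TIEN_MAX_ASA", "VDW_RADII"]

#: Tien et al. theoretical maximum ASA (A^2) per residue, one-letter keyed
TIEN_MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "SE": 1.90}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Residue:
    index: int
    aa: str                                   # one-letter code
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray                        # (n_atoms, 3)
    confidence: float = 0.0                   # pLDDT from the B-factor column


@dataclass
class StructureModel:
    """Ordered residues of one chain with atom coordinates."""

    name: str
    residues: list[Residue] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        last = 0
        for r in self.residues:
            if r.index <= last:
                raise ValueError("residue indices must be strictly increasing")
            last = r.index
            if len(r.coords) == 0:
                raise ValueError(f"residue {r.index} has no atoms")
            if not np.all(np.isfinite(r.coords)):
                raise ValueError(f"residue {r.index} has non-finite coords")

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def atom_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(coords, vdw radii, residue row index) flattened over atoms."""
        coords, radii, rid = [], [], []
        for i, r in enumerate(self.residues):
            for el, xyz in zip(r.elements, r.coords):
                el = el.upper()
                if el not in VDW_RADII:
                    raise ValueError(
                        f"unknown element {el!r} in residue {r.index}"
                    )
                coords.append(xyz)
                radii.append(VDW_RADII[el])
                rid.append(i)
        return (np.asarray(coords, dtype=float), np.asarray(radii),
                np.asarray(rid))

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "StructureModel":
        """Rigidly moved copy (for invariance checks)."""
        res = []
        for r in self.residues:
            res.append(Residue(r.index, r.aa, list(r.atom_names),
                               list(r.elements),
                               r.coords @ rotation.T + translation,
                               r.confidence))
        return StructureModel(self.name, res)


def read_structure(path, name: Optional[str] = None) -> StructureModel:
    """Read the first chain of a PDB or mmCIF file via gemmi."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chain = st[0][0]
    residues = []
    for res in chain:
        aa = THREE_TO_ONE.get(res.name.upper(), "X")
        names, elements, coords, bfs = [], [], [], []
        for atom in res:
            names.append(atom.name)
            elements.append(atom.element.name.upper() or atom.name[0])
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            bfs.append(atom.b_iso)
        residues.append(Residue(res.seqid.num, aa, names, elements,
                                np.asarray(coords), float(np.mean(bfs))))
    return StructureModel(name or str(path), residues)


# ------------------------------------------------------------- Shrake-Rupley

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _molecular_axes(coords: np.ndarray) -> np.ndarray:
    """Deterministic molecule-fixed frame from the coordinate covariance.

    Orienting the sampling sphere in this frame (instead of the lab
    frame) makes ASA/depth exactly invariant under rigid motions of the
    input, not just up to quadrature noise.
    """
    x = coords - coords.mean(axis=0)
    _, vecs = np.linalg.eigh(np.cov(x.T) if len(x) > 1 else np.eye(3))
    axes = vecs[:, ::-1].T                       # rows, largest spread first
    for k in range(3):                           # fix sign deterministically
        proj = x @ axes[k]
        if proj[np.argmax(np.abs(proj))] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:                  # keep a right-handed frame
        axes[2] = -axes[2]
    return axes


def _sasa_points(model: StructureModel, probe_radius: float,
                 n_points: int) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                         list[np.ndarray]]:
    """Per-atom ASA plus the accessible sphere points of every atom."""
    coords, radii, rid = model.atom_arrays()
    unit = _fibonacci_sphere(n_points) @ _molecular_axes(coords)
    tree = cKDTree(coords)
    rmax = radii.max()
    asa = np.zeros(len(coords))
    acc_points: list[np.ndarray] = []
    for i in range(len(coords)):
        r_i = radii[i] + probe_radius
        pts = coords[i] + r_i * unit
        neigh = tree.query_ball_point(coords[i], r_i + rmax + probe_radius)
        neigh = [j for j in neigh if j != i]
        free = np.ones(n_points, dtype=bool)
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)] + probe_radius
            d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
            free = ~(d2 < (nr ** 2)[None, :]).any(axis=1)
        asa[i] = 4.0 * np.pi * r_i ** 2 * free.sum() / n_points
        acc_points.append(pts[free])
    return asa, rid, radii, acc_points


def compute_surface(model: StructureModel, probe_radius: float = 1.4,
                    n_points: int = 960) -> pd.DataFrame:
    """Per-residue (asa, rsa) by Shrake-Rupley sampling.

    RSA is ASA over the Tien et al. theoretical maximum for the residue's
    amino acid and is deliberately not capped at 1 (pseudo-atom models
    and chain termini can exceed the tripeptide reference).
    """
    asa_atoms, rid, _, _ = _sasa_points(model, probe_radius, n_points)
    return _surface_frame(model, asa_atoms, rid)


def _surface_frame(model: StructureModel, asa_atoms: np.ndarray,
                   rid: np.ndarray) -> pd.DataFrame:
    n = len(model.residues)
    asa = np.zeros(n)
    np.add.at(asa, rid, asa_atoms)
    rows = []
    for i, r in enumerate(model.residues):
        max_asa = TIEN_MAX_ASA.get(r.aa, np.mean(list(TIEN_MAX_ASA.values())))
        rows.append({"residue_index": r.index, "aa": r.aa,
                     "asa": asa[i], "rsa": asa[i] / max_asa,
                     "confidence": r.confidence})
    return pd.DataFrame(rows)


def compute_depth(model: StructureModel, probe_radius: float = 1.4,
                  n_points: int = 960) -> pd.Series:
    """Approximate residue depth (A) from the accessible surface.

    Per-atom depth is the distance to the nearest accessible sphere point
    (a probe-center position) minus the probe radius, floored at zero;
    residue depth is the mean over its atoms.
    """
    coords, _, rid, = model.atom_arrays()[:3]
    _, _, _, acc_points = _sasa_points(model, probe_radius, n_points)
    surface = np.vstack([p for p in acc_points if len(p)]) \
        if any(len(p) for p in acc_points) else np.empty((0, 3))
    if not len(surface):
        raise ValueError("model has no accessible surface")
    tree = cKDTree(surface)
    d, _ = tree.query(coords)
    depth_atom = np.maximum(d - probe_radius, 0.0)
    n = len(model.residues)
    depth = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(depth, rid, depth_atom)
    np.add.at(counts, rid, 1.0)
    return pd.Series(depth / counts, name="depth")


def residue_profile(model: StructureModel, probe_radius: float = 1.4,
                    n_points: int = 960, rsa_cut: float = 0.7,
                    depth_cut: float = 3.6, window: int = 25) -> pd.DataFrame:
    """Full per-residue profile: asa, rsa, depth, flags and window disorder."""
    asa_atoms, rid, _, acc_points = _sasa_points(model, probe_radius, n_points)
    prof = _surface_frame(model, asa_atoms, rid)
    coords = model.atom_arrays()[0]
    surface = np.vstack([p for p in acc_points if len(p)]) \
        if any(len(p) for p in acc_points) else np.empty((0, 3))
    if len(surface):
        d, _ = cKDTree(surface).query(coords)
        depth_atom = np.maximum(d - probe_radius, 0.0)
        n = len(model.residues)
        dsum, cnt = np.zeros(n), np.zeros(n)
        np.add.at(dsum, rid, depth_atom)
        np.add.at(cnt, rid, 1.0)
        prof["depth"] = dsum / cnt
    else:
        prof["depth"] = np.nan
    prof["window_disorder"] = window_disorder(prof["rsa"].to_numpy(), window)
    prof["is_accessible_lys"] = (prof["aa"] == "K") & (prof["rsa"] > rsa_cut)
    prof["is_surface_lys"] = (prof["aa"] == "K") & (prof["depth"] < depth_cut)
    return prof


def accessible_lysines(profile: pd.DataFrame, rsa_cut: float = 0.7,
                       depth_cut: float = 3.6) -> tuple[int, int, list[int]]:
    """(n_surface_lys, n_accessible_lys, accessible indices).

    Surface lysines have depth strictly below ``depth_cut``; accessible
    lysines have RSA strictly above ``rsa_cut``.
    """
    lys = profile[profile["aa"] == "K"]
    n_surface = int((lys["depth"] < depth_cut).sum())
    acc = lys[lys["rsa"] > rsa_cut]
    return n_surface, len(acc), acc["residue_index"].tolist()


def window_disorder(rsa: Sequence[float], window: int = 25) -> np.ndarray:
    """Mean RSA in a centered window, truncated at chain ends, clamped [0,1].

    The window-averaged accessibility is the structure-based disorder
    proxy: long stretches of highly exposed residues behave as
    disordered, tightly packed stretches as ordered.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < 3:
        raise ValueError("window must be >= 3")
    rsa = np.asarray(rsa, dtype=float)
    half = window // 2
    n = len(rsa)
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(rsa)])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)   # truncated-window mean
    return np.clip(out, 0.0, 1.0)


def median_accessible_lys_disorder(profile: pd.DataFrame) -> float:
    """Per-protein summary: median window disorder over accessible Lys."""
    acc = profile[profile["is_accessible_lys"]]
    if acc.empty:
        return float("nan")
    return float(acc["window_disorder"].median())


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var() == 0 and b.var() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


# ------------------------------------------------------- LIS classification

@dataclass
class LISRecord:
    """AlphaFold-Multimer local interaction score for one bait-prey pair."""

    bait_id: str
    prey_id: str
    lis: float
    lia: float
    klass: str = ""

    @property
    def direct_ppi_evidence(self) -> bool:
        return self.lis > 0


def classify_lis(records: list[LISRecord],
                 strong: tuple[float, float] = (0.203, 3432.0),
                 positive: tuple[float, float] = (0.073, 1610.0),
                 ) -> list[LISRecord]:
    """Threshold classification of predicted-complex interaction scores.

    strong_positive: LIS >= 0.203 and LIA >= 3432; positive: LIS >= 0.073
    and LIA >= 1610; otherwise negative. Bounds are inclusive.
    """
    for r in records:
        if not (np.isfinite(r.lis) and np.isfinite(r.lia)):
            raise ValueError(f"non-finite LIS/LIA for {r.bait_id}-{r.prey_id}")
        if r.lis >= strong[0] and r.lia >= strong[1]:
            r.klass = "strong_positive"
        elif r.lis >= positive[0] and r.lia >= positive[1]:
            r.klass = "positive"
        else:
            r.klass = "negative"
    return records
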