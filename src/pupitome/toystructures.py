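"""Generated toy structures with controlled lysine burial and disorder.

Pseudo-structures of three folds, built from backbone + CB pseudo-atoms
with standard van der Waals radii — enough to produce sharp contrasts in
ASA, RSA and depth without a rotamer library:

* ``globule``: residues packed on a compact cubic lattice filled from
  the center outward, so low residue indices are buried and the shell is
  exposed (chain connectivity is not physical; these are accessibility
  phantoms, not folds);
* ``extended``: a maximally spread extended chain, every residue exposed;
* ``helix_bundle``: ideal alpha-helices (1.5 A rise, 100 deg/residue)
  laid side by side.

Per-residue confidence is written to the B-factor column, mirroring how
predicted models carry pLDDT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .surface import ONE_TO_THREE, Residue, StructureModel

__all__ = ["ToyStructureSpec", "generate_toy_structures", "build_toy_model",
           "write_pdb"]

_FOLDS = ("globule", "helix_bundle", "extended")

# local atom offsets (A) within a residue, roughly backbone-shaped
_ATOM_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.array([0.00, 0.00, 0.00]),
    "C": np.array([1.20, 0.60, 0.00]),
    "O": np.array([1.40, 1.70, 0.30]),
    "CB": np.array([0.00, -1.30, 0.70]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class ToyStructureSpec:
    """``tail_res`` > 0 appends that many residues as an extended tail
    protruding from a globule — the two-part phantom contrasting a buried
    core lysine against an exposed, disordered tail lysine."""

    name: str
    n_res: int
    lys_positions: Sequence[int] = field(default_factory=list)
    fold: str = "globule"
    plddt_profile: Optional[Sequence[float]] = None   # scalar-like or per-res
    tail_res: int = 0

    def validate(self) -> None:
        if self.n_res < 5:
            raise ValueError("n_res must be >= 5")
        if self.fold not in _FOLDS:
            raise ValueError(f"fold must be one of {_FOLDS}")
        if not 0 <= self.tail_res < self.n_res:
            raise ValueError("tail_res must be in [0, n_res)")
        if self.tail_res and self.fold != "globule":
            raise ValueError("tail_res only applies to the globule fold")
        for p in self.lys_positions:
            if not 1 <= p <= self.n_res:
                raise ValueError(f"lys position {p} outside 1..{self.n_res}")


def _lattice_sites(n: int, spacing: float = 3.5) -> np.ndarray:
    """First ``n`` cubic-lattice sites sorted by distance from the origin."""
    m = 1
    while (2 * m + 1) ** 3 < n:
        m += 1
    ax = np.arange(-m, m + 1)
    grid = np.array(np.meshgrid(ax, ax, ax)).reshape(3, -1).T * spacing
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0],
                        (grid ** 2).sum(axis=1)))
    return grid[order[:n]]


#: residue spacing (A) of the spread extended phantom chain; deliberately
#: wider than a physical beta strand so every pseudo-residue clears the
#: RSA > 0.7 accessibility threshold despite lacking side-chain atoms
EXTENDED_RISE = 6.5


def _ca_positions(spec: ToyStructureSpec) -> np.ndarray:
    n = spec.n_res
    if spec.fold == "extended":
        return np.column_stack([EXTENDED_RISE * np.arange(n),
                                np.zeros(n), np.zeros(n)])
    if spec.fold == "globule":
        core = _lattice_sites(n - spec.tail_res)
        if not spec.tail_res:
            return core
        start = core[:, 0].max() + EXTENDED_RISE
        tail = np.column_stack([
            start + EXTENDED_RISE * np.arange(spec.tail_res),
            np.zeros(spec.tail_res), np.zeros(spec.tail_res)])
        return np.vstack([core, tail])
    # helix_bundle: ideal helices of ~18 residues, 10 A apart
    seg = 18
    xyz = np.zeros((n, 3))
    for i in range(n):
        k, j = divmod(i, seg)
        ang = np.deg2rad(100.0 * j)
        z = 1.5 * j if k % 2 == 0 else 1.5 * (seg - 1 - j)
        xyz[i] = [10.0 * k + 2.3 * np.cos(ang), 2.3 * np.sin(ang), z]
    return xyz


def build_toy_model(spec: ToyStructureSpec, seed: int = 0) -> StructureModel:
    """In-memory :class:`StructureModel` for a toy spec (deterministic)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    ca = _ca_positions(spec)
    jitter = rng.normal(0.0, 0.05, size=ca.shape)
    lys = set(int(p) for p in spec.lys_positions)
    plddt = spec.plddt_profile
    if plddt is None:
        plddt = [70.0] * spec.n_res
    elif np.isscalar(plddt):
        plddt = [float(plddt)] * spec.n_res

    # in the globule core the atoms of one residue stay clustered near the
    # lattice site so interior sites remain solvent-inaccessible
    n_core = spec.n_res - spec.tail_res if spec.fold == "globule" else 0
    extended_like = spec.fold == "extended" or spec.tail_res > 0
    residues = []
    for i in range(spec.n_res):
        if i < n_core:
            scale = 0.45
        elif spec.fold == "extended" or (extended_like and i >= n_core):
            scale = 1.5       # spread pseudo-atoms: fully exposed residues
        else:
            scale = 1.0
        aa = "K" if (i + 1) in lys else "A"
        names = ["N", "CA", "C", "O"] + (["CB"] if aa != "G" else [])
        coords = np.array([ca[i] + scale * _ATOM_OFFSETS[nm] + jitter[i]
                           for nm in names])
        residues.append(Residue(i + 1, aa, names,
                                [_ELEMENTS[nm] for nm in names],
                                coords, float(plddt[i])))
    return StructureModel(spec.name, residues)


def write_pdb(model: StructureModel, path) -> None:
    """Write ATOM records; per-residue confidence goes to the B-factor."""
    lines = []
    serial = 1
    for r in model.residues:
        res3 = ONE_TO_THREE.get(r.aa, "UNK")
        for nm, el, xyz in zip(r.atom_names, r.elements, r.coords):
            lines.append(
                f"ATOM  {serial:>5} {nm:<4} {res3:>3} A{r.index:>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{r.confidence:6.2f}          {el:>2}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_toy_structures(specs: Sequence[ToyStructureSpec], out_dir,
                            seed: int = 0) -> list[Path]:
    """Write one PDB per spec into ``out_dir``; returns the file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, spec in enumerate(specs):
        model = build_toy_model(spec, seed=seed + i)
        p = out_dir / f"{spec.name}.pdb"
        write_pdb(model, p)
        paths.append(p)
    return paths
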