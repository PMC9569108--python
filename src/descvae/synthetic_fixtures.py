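"""Self-contained synthetic SMILES corpora and planted-property tables.

Real source corpora (ZINC-scale) and curated target sets need
downloads and GPU-scale training; these fixtures emulate the
statistical structure the method assumes at desk scale: small, valid,
acyclic C/N/O molecules with short SMILES, and a property constructed
as a linear combination of standardized descriptors plus Gaussian
noise so the descriptor-property correlations are known in closed
form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_data import DescriptorTable

__all__ = ["FixtureSpec", "generate_corpus", "enumerate_molecules", "plant_property"]

_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass
class FixtureSpec:
    n_molecules: int = 200
    max_heavy_atoms: int = 8
    generator: str = "random_walk"           # "acyclic_enumeration" | "random_walk"
    elements: tuple[str, ...] = ("C", "N", "O")
    planted_descriptors: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 0.5
    seed: int = 0


def _canonical(mol: Chem.RWMol) -> str | None:
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        return Chem.MolToSmiles(m)
    except Exception:
        return None


def enumerate_molecules(max_heavy_atoms: int,
                        elements: tuple[str, ...] = ("C", "N", "O")) -> list[str]:
    """All distinct acyclic single-bonded molecules up to a size.

    Breadth-first growth: every molecule of size k is extended by one
    new atom bonded to each atom with free valence, deduplicated by
    canonical SMILES.  This is exhaustive for trees over the given
    elements (hydrogens implicit).
    """
    if max_heavy_atoms < 1:
        raise ValueError("max_heavy_atoms must be >= 1")
    seen: set[str] = set()
    frontier: list[str] = []
    for el in elements:
        smi = Chem.MolToSmiles(Chem.MolFromSmiles(el if el == "C" else el))
        if smi not in seen:
            seen.add(smi)
            frontier.append(smi)
    for _ in range(max_heavy_atoms - 1):
        next_frontier: list[str] = []
        for smi in frontier:
            base = Chem.MolFromSmiles(smi)
            for atom in base.GetAtoms():
                free = _VALENCE[atom.GetSymbol()] - atom.GetDegree()
                if free <= 0:
                    continue
                for el in elements:
                    rw = Chem.RWMol(base)
                    new_idx = rw.AddAtom(Chem.Atom(el))
                    rw.AddBond(atom.GetIdx(), new_idx, Chem.BondType.SINGLE)
                    out = _canonical(rw)
                    if out is not None and out not in seen:
                        seen.add(out)
                        next_frontier.append(out)
        frontier = next_frontier
    return sorted(seen)


def _random_walk_corpus(spec: FixtureSpec) -> list[str]:
    rng = np.random.default_rng(spec.seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        n_atoms = int(rng.integers(2, spec.max_heavy_atoms + 1))
        rw = Chem.RWMol()
        first = str(rng.choice(list(spec.elements)))
        rw.AddAtom(Chem.Atom(first))
        ok = True
        for _ in range(n_atoms - 1):
            candidates = [a.GetIdx() for a in rw.GetAtoms()
                          if _VALENCE[a.GetSymbol()] - a.GetDegree() > 0]
            if not candidates:
                ok = False
                break
            parent = int(rng.choice(candidates))
            el = str(rng.choice(list(spec.elements)))
            idx = rw.AddAtom(Chem.Atom(el))
            rw.AddBond(parent, idx, Chem.BondType.SINGLE)
        if not ok:
            continue
        smi = _canonical(rw)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    if len(out) < spec.n_molecules:
        raise ValueError(
            f"could only generate {len(out)} distinct molecules "
            f"(requested {spec.n_molecules}) with max_heavy_atoms={spec.max_heavy_atoms}")
    return out


def generate_corpus(spec: FixtureSpec) -> list[str]:
    """Deterministic (seeded) list of distinct, valid canonical SMILES."""
    if spec.n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if spec.generator == "acyclic_enumeration":
        space = enumerate_molecules(spec.max_heavy_atoms, spec.elements)
        if spec.n_molecules > len(space):
            raise ValueError(
                f"requested {spec.n_molecules} molecules but only "
                f"{len(space)} exist up to {spec.max_heavy_atoms} heavy atoms")
        rng = np.random.default_rng(spec.seed)
        idx = rng.choice(len(space), size=spec.n_molecules, replace=False)
        return [space[i] for i in sorted(idx)]
    if spec.generator == "random_walk":
        return _random_walk_corpus(spec)
    raise ValueError(f"unknown generator {spec.generator!r}")


def plant_property(table: DescriptorTable, weights: dict[str, float],
                   noise_sd: float, seed: int) -> np.ndarray:
    """y = sum_d w_d * standardized(d) + N(0, noise_sd^2).

    Standardizing inside the construction makes the weights
    interpretable as effect sizes: for independent standardized
    descriptors, corr(d, y) = w_d / sqrt(sum w^2 + noise_sd^2).
    """
    unknown = [n for n in weights if n not in table.names]
    if unknown:
        raise KeyError(f"unknown descriptors: {unknown}")
    n = table.n_molecules
    y = np.zeros(n)
    for name, w in weights.items():
        col = table.column(name)
        sd = col.std()
        if sd == 0:
            raise ValueError(f"descriptor {name!r} is constant")
        y = y + w * (col - col.mean()) / sd
    rng = np.random.default_rng(seed)
    return y + rng.normal(0.0, noise_sd, size=n)
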