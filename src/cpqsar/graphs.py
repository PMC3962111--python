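"""Hydrogen-depleted molecular graphs and their derived matrices.

Topological descriptors are computed on the H-depleted graph: explicit
hydrogens are removed (implicit counts retained on the atoms) and, for
multi-component structures such as salts, only the largest fragment is kept
(topological distances are undefined across components).

Derived matrices:

- adjacency ``A`` (n x n, 0/1),
- topological distance ``D`` (shortest-path lengths in bonds),
- detour ``Delta`` (longest *simple*-path lengths; exact exhaustive search,
  guarded by an atom-count limit since the problem is exponential),
- edge adjacency ``E`` (bonds x bonds, nonzero where two bonds share an atom),
  optionally weighted by edge degrees or bond dipole moments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

#: Default hard cap on atoms for the exact detour-matrix search.
DETOUR_ATOM_LIMIT = 30


class GraphSizeError(ValueError):
    """Graph too large for an exact exponential-time computation."""


@dataclass
class MolecularGraph:
    """H-depleted molecular graph with cached derived matrices."""

    mol: Chem.Mol
    detour_atom_limit: int = DETOUR_ATOM_LIMIT
    _dropped_fragments: int = field(default=0, repr=False)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, detour_atom_limit: int = DETOUR_ATOM_LIMIT) -> "MolecularGraph":
        mol = Chem.RemoveHs(mol)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        dropped = 0
        if len(frags) > 1:
            largest = max(frags, key=lambda m: m.GetNumAtoms())
            dropped = len(frags) - 1
            logger.info("multi-component structure: keeping largest fragment (%d atoms), dropping %d", largest.GetNumAtoms(), dropped)
            mol = largest
        return cls(mol=mol, detour_atom_limit=detour_atom_limit, _dropped_fragments=dropped)

    @classmethod
    def from_smiles(cls, smiles: str, **kwargs) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES {smiles!r}")
        return cls.from_mol(mol, **kwargs)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def n_bonds(self) -> int:
        return self.mol.GetNumBonds()

    @cached_property
    def elements(self) -> list[str]:
        return [a.GetSymbol() for a in self.mol.GetAtoms()]

    @cached_property
    def adjacency(self) -> np.ndarray:
        return np.asarray(Chem.GetAdjacencyMatrix(self.mol), dtype=float)

    @cached_property
    def distance(self) -> np.ndarray:
        """Topological distance matrix (shortest paths, in bonds)."""
        return np.asarray(Chem.GetDistanceMatrix(self.mol), dtype=float)

    @cached_property
    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for b in self.mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            adj[i].append(j)
            adj[j].append(i)
        return adj

    @cached_property
    def detour(self) -> np.ndarray:
        """Detour matrix: longest simple-path length between each atom pair.

        Exhaustive depth-first enumeration of simple paths from each source;
        exact but exponential, hence the atom-count guard.
        """
        n = self.n_atoms
        if n > self.detour_atom_limit:
            raise GraphSizeError(
                f"detour matrix requested for {n} atoms; exact search is capped "
                f"at {self.detour_atom_limit} (raise detour_atom_limit to override)"
            )
        adj = self.neighbors
        delta = np.zeros((n, n))
        for s in range(n):
            best = delta[s]
            visited = [False] * n
            visited[s] = True

            def dfs(v: int, length: int) -> None:
                for w in adj[v]:
                    if not visited[w]:
                        if length + 1 > best[w]:
                            best[w] = length + 1
                        visited[w] = True
                        dfs(w, length + 1)
                        visited[w] = False

            dfs(s, 0)
        # symmetrize: path enumeration from each source already covers both
        # directions, but keep the max for safety
        delta = np.maximum(delta, delta.T)
        if not np.all(delta >= self.distance):
            raise AssertionError("detour matrix violated Delta >= D")
        return delta

    @cached_property
    def sssr(self) -> list[tuple[int, ...]]:
        """Smallest set of smallest rings, as atom-index tuples."""
        return [tuple(r) for r in Chem.GetSymmSSSR(self.mol)]

    @cached_property
    def edge_degrees(self) -> np.ndarray:
        """Edge degree of each bond: number of bonds adjacent to it."""
        deg = np.array([a.GetDegree() for a in self.mol.GetAtoms()], dtype=float)
        out = np.empty(self.n_bonds)
        for b in self.mol.GetBonds():
            out[b.GetIdx()] = deg[b.GetBeginAtomIdx()] + deg[b.GetEndAtomIdx()] - 2.0
        return out

    def edge_adjacency(
        self,
        weighting: str = "none",
        bond_weights: np.ndarray | None = None,
    ) -> np.ndarray:
        """Edge adjacency matrix over bonds.

        ``weighting``:

        - ``"none"``: 1 where two bonds share an atom, 0 elsewhere.
        - ``"edge_degree"``: off-diagonal entries ``1/sqrt(d_i * d_j)`` with
          ``d`` the edge degrees (diagonal zero).
        - ``"bond"``: off-diagonal 1, diagonal carries ``bond_weights``
          (e.g. bond dipole moments, Estrada-style weighting).
        """
        m = self.n_bonds
        E = np.zeros((m, m))
        bonds = list(self.mol.GetBonds())
        atoms_of = [{b.GetBeginAtomIdx(), b.GetEndAtomIdx()} for b in bonds]
        for i in range(m):
            for j in range(i + 1, m):
                if atoms_of[i] & atoms_of[j]:
                    E[i, j] = E[j, i] = 1.0
        if weighting == "none":
            return E
        if weighting == "edge_degree":
            d = self.edge_degrees
            with np.errstate(divide="ignore"):
                inv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
            return E * np.outer(inv, inv)
        if weighting == "bond":
            if bond_weights is None:
                raise ValueError("bond weighting requires bond_weights")
            E[np.diag_indices(m)] = np.asarray(bond_weights, dtype=float)
            return E
        raise ValueError(f"unknown edge weighting {weighting!r}")
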