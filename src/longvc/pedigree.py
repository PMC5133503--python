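"""Pedigree data model, validation, and theoretical kinship.

A pedigree is an ordered collection of individuals with optional parent
links.  Validation establishes a topological order (parents before
offspring) and checks referential and sex consistency.  The kinship
coefficient phi(i, j) is the probability that one allele drawn at random
from i and one from j are identical by descent; the matrix ``Phi`` over
all pairs drives every variance-component model in this package through
the additive relationship matrix ``2 * Phi``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "CycleError",
    "validate_pedigree",
    "compute_kinship",
]

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Structural, referential, or consistency problem in a pedigree."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are ``None`` for founders.  Ids are opaque
    strings; numeric values carry no meaning.  ``family_id`` groups
    individuals into putative pedigrees but connectivity is re-derived
    during validation, so cross-family marriages in a file are handled.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = UNKNOWN
    family_id: str = "0"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """An ordered collection of individuals, optionally validated.

    After :func:`validate_pedigree` the member list is in topological
    order (every parent precedes its offspring) and ``validated`` is set.
    """

    members: list[Individual]
    validated: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {ind.id: i for i, ind in enumerate(self.members)}
        if len(self._index) != len(self.members):
            seen: set[str] = set()
            for ind in self.members:
                if ind.id in seen:
                    raise PedigreeError(f"duplicate individual id {ind.id!r}")
                seen.add(ind.id)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def __getitem__(self, ind_id: str) -> Individual:
        return self.members[self._index[ind_id]]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def components(self) -> list[list[str]]:
        """Connected components (true pedigrees), each in member order.

        Connectivity is via parent-offspring edges, so two file families
        joined by a marriage with offspring form one component.
        """
        parent = {m.id: m.id for m in self.members}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: str, b: str) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for m in self.members:
            for p in (m.father_id, m.mother_id):
                if p is not None:
                    union(m.id, p)
        groups: dict[str, list[str]] = {}
        for m in self.members:
            groups.setdefault(find(m.id), []).append(m.id)
        return list(groups.values())


def _toposort(ped: Pedigree) -> list[Individual]:
    """Kahn's algorithm over parent->offspring edges; raises on cycles."""
    by_id = {m.id: m for m in ped.members}
    n_pending = {m.id: sum(p is not None for p in (m.father_id, m.mother_id))
                 for m in ped.members}
    children: dict[str, list[str]] = {m.id: [] for m in ped.members}
    for m in ped.members:
        for p in (m.father_id, m.mother_id):
            if p is not None:
                if p not in by_id:
                    raise PedigreeError(
                        f"individual {m.id!r} names parent {p!r} "
                        "which is not in the pedigree"
                    )
                children[p].append(m.id)
    # stable order: process ready individuals in original file order
    order: list[Individual] = []
    ready = [m.id for m in ped.members if n_pending[m.id] == 0]
    while ready:
        nxt: list[str] = []
        for ind_id in ready:
            order.append(by_id[ind_id])
            for ch in children[ind_id]:
                n_pending[ch] -= 1
                if n_pending[ch] == 0:
                    nxt.append(ch)
        ready = nxt
    if len(order) != len(ped.members):
        stuck = sorted(i for i, k in n_pending.items() if k > 0)
        raise CycleError(
            f"pedigree contains a cycle involving individuals {stuck}"
        )
    return order


def validate_pedigree(ped: Pedigree) -> Pedigree:
    """Validate structure and return a topologically sorted copy.

    Checks: both parents present or both missing, parent ids resolve,
    acyclicity, and that named fathers/mothers are male/female when their
    sex is known (``unknown`` sexes are filled in from the parental role).

    Raises
    ------
    PedigreeError
        On dangling parent ids, half-specified parents, or sex conflicts.
    CycleError
        If an individual is its own ancestor.
    """
    if not ped.members:
        raise PedigreeError("pedigree has no individuals")
    for m in ped.members:
        if (m.father_id is None) != (m.mother_id is None):
            raise PedigreeError(
                f"individual {m.id!r} has exactly one parent specified; "
                "supply both or neither (the PED reader can synthesize "
                "anonymous founders)"
            )
        if m.father_id is not None and m.father_id == m.mother_id:
            raise PedigreeError(
                f"individual {m.id!r} lists the same id for both parents"
            )
    order = _toposort(ped)

    # sex consistency: a named father must not be female, and vice versa.
    role: dict[str, str] = {}
    for m in order:
        if m.father_id is not None:
            role.setdefault(m.father_id, MALE)
            if role[m.father_id] != MALE:
                raise PedigreeError(
                    f"individual {m.father_id!r} appears as both father and mother"
                )
        if m.mother_id is not None:
            role.setdefault(m.mother_id, FEMALE)
            if role[m.mother_id] != FEMALE:
                raise PedigreeError(
                    f"individual {m.mother_id!r} appears as both father and mother"
                )
    fixed: list[Individual] = []
    for m in order:
        want = role.get(m.id)
        if want is not None:
            if m.sex == UNKNOWN:
                m = replace(m, sex=want)
            elif m.sex != want:
                raise PedigreeError(
                    f"individual {m.id!r} is recorded as {m.sex} but is "
                    f"named as a {'father' if want == MALE else 'mother'}"
                )
        fixed.append(m)
    return Pedigree(fixed, validated=True)


@dataclass
class KinshipMatrix:
    """Kinship coefficients over an id ordering.

    ``phi`` is symmetric with diagonal ``0.5 * (1 + F_i)`` where ``F_i``
    is the inbreeding coefficient; ``2 * phi`` is the additive genetic
    relationship matrix used in the trait covariance.
    """

    ids: list[str]
    phi: np.ndarray
    blocks: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}
        if not self.blocks:
            self.blocks = [np.arange(len(self.ids))]

    def coeff(self, a: str, b: str) -> float:
        return float(self.phi[self._index[a], self._index[b]])

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        idx = np.array([self._index[i] for i in ids])
        sub = self.phi[np.ix_(idx, idx)]
        return KinshipMatrix(list(ids), sub, blocks=_blocks_from_phi(sub))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def to_long(self):
        import pandas as pd

        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i, n):
                rows.append((self.ids[i], self.ids[j], self.phi[i, j]))
        return pd.DataFrame(rows, columns=["id1", "id2", "phi"])


def _blocks_from_phi(phi: np.ndarray) -> list[np.ndarray]:
    """Connected components of the nonzero pattern of a kinship matrix."""
    n = phi.shape[0]
    seen = np.zeros(n, dtype=bool)
    blocks = []
    adj = phi != 0.0
    for s in range(n):
        if seen[s]:
            continue
        stack = [s]
        comp = []
        seen[s] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            nbrs = np.nonzero(adj[v] & ~seen)[0]
            seen[nbrs] = True
            stack.extend(nbrs.tolist())
        blocks.append(np.array(sorted(comp)))
    return blocks


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the recursive tabular method.

    Over a topological order: founders get ``phi = 0.5`` on the diagonal
    and 0 with all earlier individuals; a non-founder i gets
    ``phi(i, i) = 0.5 + 0.5 * phi(father, mother)`` and
    ``phi(i, j) = 0.5 * (phi(father, j) + phi(mother, j))`` for earlier j.
    Exact (no path counting), O(n^2), and supports inbreeding loops.

    Requires a validated pedigree (the recursion needs parents first).
    """
    if not ped.validated:
        raise PedigreeError("compute_kinship requires a validated pedigree; "
                            "call validate_pedigree first")
    n = len(ped)
    idx = {m.id: i for i, m in enumerate(ped.members)}
    phi = np.zeros((n, n))
    for i, m in enumerate(ped.members):
        if m.is_founder:
            phi[i, i] = 0.5
            continue
        f, mo = idx[m.father_id], idx[m.mother_id]
        phi[i, i] = 0.5 + 0.5 * phi[f, mo]
        row = 0.5 * (phi[f, :i] + phi[mo, :i])
        phi[i, :i] = row
        phi[:i, i] = row
    blocks = [np.array(sorted(idx[c] for c in comp)) for comp in ped.components()]
    blocks.sort(key=lambda b: b[0])
    return KinshipMatrix(ped.ids, phi, blocks=blocks)
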