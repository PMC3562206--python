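"""Pedigree and genotype data model, PED/MAP readers, focus-pedigree decomposition.

The pedigree is decomposed into *focus pedigrees*: local units of one focus
individual plus its ancestors ``k`` generations back (k = 1 or 2).  Each focus
pedigree carries its own small hidden Markov chain, while per-individual
parameter tables (skewness, sureness) are shared between all focus pedigrees
in which an individual appears, which is how global information propagates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MapOrderError, StructureError, UnsupportedError

MISSING = -1  # integer code for a missing allele

SEX_MALE = "male"
SEX_FEMALE = "female"
SEX_UNKNOWN = "unknown"

_PED_SEX = {"1": SEX_MALE, "2": SEX_FEMALE}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``sire_id``/``dam_id`` are either both set (non-founder) or both ``None``
    (founder); a half-specified parent pair is rejected at construction of the
    enclosing :class:`Pedigree`.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = SEX_UNKNOWN
    genotyped: bool = True

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None


class Pedigree:
    """Ordered collection of individuals with parents preceding offspring.

    Any input order is accepted; the constructor topologically sorts and
    verifies that every referenced parent exists and that no individual is its
    own ancestor.
    """

    def __init__(self, individuals: Iterable[Individual]):
        members = list(individuals)
        by_id: dict[str, Individual] = {}
        for ind in members:
            if ind.id in by_id:
                raise StructureError(f"duplicate individual id {ind.id!r}")
            if (ind.sire_id is None) != (ind.dam_id is None):
                raise StructureError(
                    f"individual {ind.id!r} has only one recorded parent"
                )
            by_id[ind.id] = ind
        for ind in members:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in by_id:
                    raise StructureError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        self.individuals: list[Individual] = self._toposort(members, by_id)
        self._index = {ind.id: i for i, ind in enumerate(self.individuals)}
        self.generation_index: dict[str, int] = {}
        for ind in self.individuals:
            if ind.is_founder:
                self.generation_index[ind.id] = 0
            else:
                self.generation_index[ind.id] = 1 + max(
                    self.generation_index[ind.sire_id],
                    self.generation_index[ind.dam_id],
                )
        self._children: dict[str, list[str]] = {ind.id: [] for ind in self.individuals}
        for ind in self.individuals:
            if not ind.is_founder:
                self._children[ind.sire_id].append(ind.id)
                self._children[ind.dam_id].append(ind.id)

    @staticmethod
    def _toposort(
        members: list[Individual], by_id: dict[str, Individual]
    ) -> list[Individual]:
        order: list[Individual] = []
        state: dict[str, int] = {}  # 0 unvisited / 1 on stack / 2 done

        for root in members:
            if state.get(root.id):
                continue
            stack = [(root, False)]
            while stack:
                ind, processed = stack.pop()
                if processed:
                    state[ind.id] = 2
                    order.append(ind)
                    continue
                if state.get(ind.id) == 2:
                    continue
                if state.get(ind.id) == 1:
                    raise StructureError(
                        f"pedigree cycle involving individual {ind.id!r}"
                    )
                state[ind.id] = 1
                stack.append((ind, True))
                for pid in (ind.dam_id, ind.sire_id):
                    if pid is not None and state.get(pid) != 2:
                        if state.get(pid) == 1:
                            raise StructureError(
                                f"pedigree cycle involving individual {pid!r}"
                            )
                        stack.append((by_id[pid], False))
        return order

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        return self.individuals[self._index[ind_id]]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._index

    def index_of(self, ind_id: str) -> int:
        return self._index[ind_id]

    def children_of(self, ind_id: str) -> list[str]:
        return list(self._children[ind_id])

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    def matings(self) -> list[tuple[str, str, list[str]]]:
        """Distinct (sire, dam) pairs with their joint offspring, in topological order."""
        seen: dict[tuple[str, str], list[str]] = {}
        order: list[tuple[str, str]] = []
        for ind in self.individuals:
            if ind.is_founder:
                continue
            key = (ind.sire_id, ind.dam_id)
            if key not in seen:
                seen[key] = []
                order.append(key)
            seen[key].append(ind.id)
        return [(s, d, seen[(s, d)]) for s, d in order]


class MarkerMap:
    """Ordered markers of a single chromosome with genetic positions in cM.

    ``alleles_per_marker`` holds the total allele set :math:`A_m` per marker
    (sorted allele code strings).  It may be supplied up front or learned from
    the genotype data when a PED file is read.
    """

    def __init__(
        self,
        marker_ids: Sequence[str],
        positions_cM: Sequence[float],
        alleles_per_marker: Sequence[Sequence[str]] | None = None,
        chromosome: str = "1",
    ):
        if len(marker_ids) != len(positions_cM):
            raise MapOrderError("marker_ids and positions_cM differ in length")
        pos = np.asarray(positions_cM, dtype=float)
        if pos.size and np.any(np.diff(pos) < 0):
            raise MapOrderError("genetic positions must be nondecreasing")
        self.marker_ids = list(marker_ids)
        self.positions_cM = pos
        self.chromosome = chromosome
        if alleles_per_marker is None:
            self.alleles_per_marker: list[tuple[str, ...]] | None = None
        else:
            if len(alleles_per_marker) != len(self.marker_ids):
                raise FormatError("alleles_per_marker length mismatch")
            self.alleles_per_marker = [
                tuple(sorted(set(map(str, a)))) for a in alleles_per_marker
            ]
            if any(len(a) < 1 for a in self.alleles_per_marker):
                raise FormatError("every marker needs at least one allele code")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def intervals_cM(self) -> np.ndarray:
        """Distances between adjacent markers, in cM (length ``n_markers - 1``)."""
        return np.diff(self.positions_cM)

    def n_alleles(self) -> np.ndarray:
        if self.alleles_per_marker is None:
            raise FormatError("allele sets not yet known for this map")
        return np.array([len(a) for a in self.alleles_per_marker], dtype=int)

    def encode_allele(self, marker: int, code: str) -> int:
        try:
            return self.alleles_per_marker[marker].index(code)
        except ValueError:
            raise FormatError(
                f"allele code {code!r} not in A_m for marker "
                f"{self.marker_ids[marker]!r}"
            ) from None

    def decode_allele(self, marker: int, value: int) -> str:
        if value == MISSING:
            return "."
        return self.alleles_per_marker[marker][value]


class GenotypeMatrix:
    """Recorded, unordered allele pairs per individual per marker.

    Stored as an integer array of shape ``(n_individuals, n_markers, 2)`` with
    allele codes indexing into ``MarkerMap.alleles_per_marker`` and
    :data:`MISSING` (=-1) for absent data.  Both entries of a pair are present
    or both missing; a half-missing recorded pair is treated as fully missing.
    """

    def __init__(self, ids: Sequence[str], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 3 or codes.shape[2] != 2 or codes.shape[0] != len(ids):
            raise FormatError("genotype code array must be (n_individuals, n_markers, 2)")
        half = (codes == MISSING).sum(axis=2) == 1
        if np.any(half):
            codes = codes.copy()
            codes[half] = MISSING
        self.ids = list(ids)
        self.codes = codes
        self._index = {s: i for i, s in enumerate(self.ids)}

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def row(self, ind_id: str) -> np.ndarray:
        return self.codes[self._index[ind_id]]

    def is_missing(self, ind_id: str) -> np.ndarray:
        return self.row(ind_id)[:, 0] == MISSING

    def fully_missing(self, ind_id: str) -> bool:
        return bool(np.all(self.is_missing(ind_id)))

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.ids, self.codes.copy())


@dataclass
class FocusPedigree:
    """One focus individual plus its ancestors up to ``k`` generations back.

    Members are ordered deterministically: grandparents first (paternal side
    before maternal, grandfather before grandmother), then father, then
    mother, then the focus individual last — the focus individual carries no
    state bit.  ``member_weight_divisors[i]`` is the divisor applied to
    parameter updates flowing from this pedigree to member ``i``: 1 for
    first-level parents and the focus, and ``1 + n_offspring(intermediate
    parent)`` for grandparents, so that each child lineage contributes equal
    total weight to a grandparent.
    """

    focus: Individual
    members: list[Individual]
    k: int
    roles: list[str]  # per member: "grandparent" | "parent" | "focus"
    member_weight_divisors: np.ndarray

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def weight_divisor(self) -> float:
        """Divisor for grandparent-level updates (1.0 when no grandparents)."""
        divs = [
            d
            for d, r in zip(self.member_weight_divisors, self.roles)
            if r == "grandparent"
        ]
        return float(divs[0]) if divs else 1.0

    @property
    def meiosis_edges(self) -> list[tuple[int, int, int]]:
        """State-bit edges ``(ancestor_member_index, child_member_index, side)``.

        One edge per meiosis tracked by the chain, in deterministic order:
        receiving members in member order, paternal edge (side 0) before
        maternal (side 1).  The number of edges is ``n_members - 1``.
        """
        idx = {ind.id: i for i, ind in enumerate(self.members)}
        edges: list[tuple[int, int, int]] = []
        for j, ind in enumerate(self.members):
            if ind.is_founder:
                continue
            if ind.sire_id in idx and ind.dam_id in idx:
                edges.append((idx[ind.sire_id], j, 0))
                edges.append((idx[ind.dam_id], j, 1))
        return edges


def decompose(pedigree: Pedigree, k: int = 1) -> list[FocusPedigree]:
    """Split a pedigree into one focus pedigree per non-founder individual.

    Members are truncated at pedigree founders: a founder parent contributes
    no grandparents even when ``k=2``.  Grandparent update weights are set to
    ``1 + n_offspring(intermediate parent)`` so that every child lineage of a
    grandparent carries equal total weight.
    """
    if k not in (1, 2):
        raise UnsupportedError(
            f"k={k} unsupported: the state space grows as 2^(N-1); already k=3 "
            "would require 16,384 states"
        )
    out: list[FocusPedigree] = []
    for focus in pedigree.nonfounders:
        father = pedigree[focus.sire_id]
        mother = pedigree[focus.dam_id]
        members: list[Individual] = []
        roles: list[str] = []
        divisors: list[float] = []
        if k == 2:
            for parent in (father, mother):
                if not parent.is_founder:
                    div = 1.0 + len(pedigree.children_of(parent.id))
                    for gp_id in (parent.sire_id, parent.dam_id):
                        members.append(pedigree[gp_id])
                        roles.append("grandparent")
                        divisors.append(div)
        # with k=2 an individual receives updates both from its own chain (as
        # a first-level parent) and from its children's chains (as a
        # grandparent); weighting both by 1/(1 + n_offspring(focus)) keeps
        # every child lineage's total contribution equal
        parent_div = 1.0
        if k == 2:
            parent_div = 1.0 + len(pedigree.children_of(focus.id))
        for parent in (father, mother):
            members.append(parent)
            roles.append("parent")
            divisors.append(parent_div)
        members.append(focus)
        roles.append("focus")
        divisors.append(1.0)
        out.append(
            FocusPedigree(
                focus=focus,
                members=members,
                k=k,
                roles=roles,
                member_weight_divisors=np.array(divisors),
            )
        )
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_map(path) -> MarkerMap:
    """Read a MAP file: ``chromosome  marker_id  position_cM`` per line.

    A single chromosome per map is supported; positions must be nondecreasing.
    """
    chroms: list[str] = []
    ids: list[str] = []
    pos: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chroms.append(fields[0])
            ids.append(fields[1])
            # tolerate 4-column PLINK maps (bp position last)
            pos.append(float(fields[2]))
    if len(set(chroms)) > 1:
        raise UnsupportedError(
            "multiple chromosomes in one map; run each chromosome separately"
        )
    return MarkerMap(ids, pos, chromosome=chroms[0] if chroms else "1")


def read_ped(path, marker_map: MarkerMap) -> tuple[Pedigree, GenotypeMatrix]:
    """Read a whitespace-delimited PED file against a marker map.

    Columns: family, id, sire, dam, sex, phenotype, then two allele columns
    per marker; ``0`` denotes a missing allele and a founder parent.  The
    phenotype column is ignored.  When the map carries allele sets, codes are
    validated against them; otherwise the sets are learned from the file.
    """
    n_markers = marker_map.n_markers
    rows: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{path}:{lineno}: expected {6 + 2 * n_markers} columns, "
                    f"got {len(fields)}"
                )
            _, ind_id, sire, dam, sex, _ = fields[:6]
            alleles = fields[6:]
            rows.append((ind_id, sire, dam, sex, alleles))

    learn = marker_map.alleles_per_marker is None
    if learn:
        observed: list[set[str]] = [set() for _ in range(n_markers)]
        for _, _, _, _, alleles in rows:
            for m in range(n_markers):
                for a in (alleles[2 * m], alleles[2 * m + 1]):
                    if a != "0":
                        observed[m].add(a)
        marker_map.alleles_per_marker = [
            tuple(sorted(obs)) if obs else ("1",) for obs in observed
        ]

    individuals: list[Individual] = []
    codes = np.full((len(rows), n_markers, 2), MISSING, dtype=np.int16)
    ids: list[str] = []
    for i, (ind_id, sire, dam, sex, alleles) in enumerate(rows):
        ids.append(ind_id)
        any_typed = False
        for m in range(n_markers):
            a0, a1 = alleles[2 * m], alleles[2 * m + 1]
            if a0 == "0" or a1 == "0":
                continue  # half-missing pairs treated as fully missing
            codes[i, m, 0] = marker_map.encode_allele(m, a0)
            codes[i, m, 1] = marker_map.encode_allele(m, a1)
            any_typed = True
        individuals.append(
            Individual(
                id=ind_id,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=_PED_SEX.get(sex, SEX_UNKNOWN),
                genotyped=any_typed,
            )
        )
    pedigree = Pedigree(individuals)
    # reorder genotype rows to match the pedigree's topological order
    order = [ids.index(ind.id) for ind in pedigree.individuals]
    genotypes = GenotypeMatrix([ids[i] for i in order], codes[order])
    return pedigree, genotypes


_PHASED_COLUMNS = [
    "individual",
    "marker",
    "allele0",
    "allele1",
    "skewness",
    "sureness0",
    "sureness1",
    "refused",
]


def write_phased(path, result: "PhasedResult") -> None:
    """Write a :class:`~sibphase.calling.PhasedResult` as TSV.

    One row per individual per marker (markers reported 1-based); refused
    markers emit ``.`` alleles and ``refused=1``.  Round-trips losslessly
    through :func:`read_phased`.
    """
    result.to_frame().to_csv(path, sep="\t", index=False, columns=_PHASED_COLUMNS)


def read_phased(path) -> pd.DataFrame:
    """Read a phased TSV written by :func:`write_phased`."""
    df = pd.read_csv(
        path, sep="\t", dtype={"individual": str, "allele0": str, "allele1": str}
    )
    missing = [c for c in _PHASED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"phased file lacks columns {missing}")
    return df


def write_ped(path, pedigree: Pedigree, genotypes: GenotypeMatrix,
              marker_map: MarkerMap) -> None:
    """Write pedigree + genotypes in the PED dialect accepted by :func:`read_ped`."""
    sex_code = {SEX_MALE: "1", SEX_FEMALE: "2", SEX_UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ind in pedigree.individuals:
            row = [
                "FAM1",
                ind.id,
                ind.sire_id or "0",
                ind.dam_id or "0",
                sex_code[ind.sex],
                "-9",
            ]
            codes = genotypes.row(ind.id)
            for m in range(marker_map.n_markers):
                for c in (0, 1):
                    v = codes[m, c]
                    row.append("0" if v == MISSING else marker_map.decode_allele(m, v))
            fh.write(" ".join(row) + "\n")


def write_map(path, marker_map: MarkerMap) -> None:
    """Write a MAP file (chromosome, marker id, position in cM)."""
    with open(path, "w") as fh:
        for mid, pos in zip(marker_map.marker_ids, marker_map.positions_cM):
            fh.write(f"{marker_map.chromosome} {mid} {pos:.6g}\n")
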