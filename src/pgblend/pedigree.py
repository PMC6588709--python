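"""Pedigree parsing, validation and the numerator relationship matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

#: Default tokens treated as "parent unknown" in pedigree files.
UNKNOWN = None
DEFAULT_UNKNOWN_TOKENS = ("0", "", "NA", ".")


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    ``records`` is an ordered list of ``(individual_id, sire_id, dam_id)``
    with ``None`` marking an unknown parent.  Construction validates
    uniqueness and acyclicity and re-sorts records so that every parent
    precedes its offspring.  Selfing (``sire == dam``) is permitted.
    """

    records: list[tuple[str, str | None, str | None]]
    line_ids: list[str] | None = None
    founder_ids: set[str] = field(init=False)
    _order: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = _toposort(self.records)
        self.founder_ids = {
            ind for ind, s, d in self.records if s is None and d is None
        }
        self._order = {ind: k for k, (ind, _, _) in enumerate(self.records)}

    @property
    def ids(self) -> list[str]:
        return [ind for ind, _, _ in self.records]

    @property
    def n(self) -> int:
        return len(self.records)

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        _, s, d = self.records[self._order[ind]]
        return s, d


def _toposort(
    records: list[tuple[str, str | None, str | None]],
) -> list[tuple[str, str | None, str | None]]:
    seen: dict[str, tuple[str | None, str | None]] = {}
    for ind, s, d in records:
        ind = str(ind)
        if ind in seen:
            raise PedigreeError(f"duplicate individual id {ind!r}")
        seen[ind] = (None if s is None else str(s), None if d is None else str(d))

    order: list[tuple[str, str | None, str | None]] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    for root in seen:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                s, d = seen[node]
                order.append((node, s, d))
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            s, d = seen[node]
            for parent in (d, s):
                if parent is None:
                    continue
                if state.get(parent) == 0:
                    raise PedigreeError(f"pedigree cycle involving {parent!r}")
                if state.get(parent) != 1:
                    stack.append((parent, False))
    return order


def read_pedigree(
    path: str,
    unknown_token: str | tuple[str, ...] = DEFAULT_UNKNOWN_TOKENS,
    strict: bool = False,
) -> Pedigree:
    """Read a 3-column delimited pedigree file (header ``id,sire,dam``).

    Delimiter is chosen by extension (``.tsv``/``.txt`` → tab, else comma).
    ``unknown_token`` values mark missing parents.  Parents that never occur
    as individuals are an error in strict mode; otherwise they are appended
    as founders and a warning is logged.
    """
    tokens = (unknown_token,) if isinstance(unknown_token, str) else tuple(unknown_token)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if frame.shape[1] < 3:
        raise PedigreeError(f"pedigree file {path} needs 3 columns, got {frame.shape[1]}")
    frame = frame.iloc[:, :3]

    def clean(v: str) -> str | None:
        v = v.strip()
        return None if v in tokens else v

    records = [
        (row[0].strip(), clean(row[1]), clean(row[2]))
        for row in frame.itertuples(index=False)
    ]
    declared = {r[0] for r in records}
    undeclared = sorted(
        {p for _, s, d in records for p in (s, d) if p is not None and p not in declared}
    )
    if undeclared:
        if strict:
            raise PedigreeError(
                f"parent ids never declared as individuals: {undeclared[:10]}"
            )
        logger.warning(
            "adding %d undeclared parent(s) as founders: %s",
            len(undeclared),
            undeclared[:10],
        )
        records = [(p, None, None) for p in undeclared] + records
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path: str, unknown_token: str = "0") -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    rows = [
        (i, s if s is not None else unknown_token, d if d is not None else unknown_token)
        for i, s, d in ped.records
    ]
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(path, sep=sep, index=False)


def numerator_relationship_matrix(
    ped: Pedigree, subset_ids: list[str] | None = None
) -> RelationshipMatrix:
    """Additive (numerator) relationship matrix by the tabular method.

    The recursion runs over the full pedigree; ``subset_ids`` restricts the
    result afterwards.  Unknown parents contribute zero relationship
    (founders are taken unrelated and non-inbred).
    """
    n = ped.n
    order = ped._order
    a = np.zeros((n, n))
    for i, (_, sire, dam) in enumerate(ped.records):
        si = order[sire] if sire is not None else -1
        di = order[dam] if dam is not None else -1
        if si >= 0 and di >= 0:
            a[i, :i] = 0.5 * (a[si, :i] + a[di, :i])
            a[i, i] = 1.0 + 0.5 * a[si, di]
        elif si >= 0:
            a[i, :i] = 0.5 * a[si, :i]
            a[i, i] = 1.0
        elif di >= 0:
            a[i, :i] = 0.5 * a[di, :i]
            a[i, i] = 1.0
        else:
            a[i, i] = 1.0
        a[:i, i] = a[i, :i]
    mat = RelationshipMatrix(ped.ids, a, kind="A")
    if subset_ids is not None:
        mat = mat.restrict(list(subset_ids))
    return mat


def inbreeding(ped: Pedigree) -> dict[str, float]:
    """Inbreeding coefficients ``F_i = a_ii - 1`` from the A recursion."""
    A = numerator_relationship_matrix(ped)
    return {i: float(A.values[k, k] - 1.0) for k, i in enumerate(A.ids)}


def full_sib_families(
    ped: Pedigree, line_ids: list[str]
) -> dict[tuple[str, ...], list[str]]:
    """Group lines into full-sib families keyed by the unordered parent pair.

    A line with one or both parents unknown forms its own singleton family
    (key ``("__single__", line_id)``).
    """
    families: dict[tuple[str, ...], list[str]] = {}
    for line in line_ids:
        if line not in ped._order:
            raise PedigreeError(f"line {line!r} not in pedigree")
        s, d = ped.parents(line)
        if s is None or d is None:
            key: tuple[str, ...] = ("__single__", line)
        else:
            key = tuple(sorted((s, d)))
        families.setdefault(key, []).append(line)
    return families
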