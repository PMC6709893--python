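"""Pedigree graphs, fullblood determination, expected breed composition.

A "fullblood" animal is one whose every ancestral path terminates in a
herdbook founder of its own breed (closed ancestry); a "purebred" in an
open herdbook may have been graded up by repeated backcrossing and is not
fullblood no matter how high its expected breed fraction.  Expected
composition halves at each meiosis: an animal's vector is the mean of its
parents', with founders contributing 100% of their breed and unknown
parents contributing an explicit "unknown" pseudo-breed (never silently
renormalized away).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

UNKNOWN = "0"          # parent-id sentinel in pedigree files
UNKNOWN_BREED = "unknown"


class PedigreeCycleError(ValueError):
    def __init__(self, cycle: list[str]):
        super().__init__(f"pedigree cycle: {' -> '.join(cycle)}")
        self.cycle = cycle


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    breed: str
    founder: bool = False

    def __post_init__(self) -> None:
        if self.founder and (self.sire is not None or self.dam is not None):
            raise ValueError(
                f"{self.id}: a herdbook founder must have unknown parents"
            )


class PedigreeGraph:
    """Animal -> (sire, dam, breed, founder flag) lookup with traversals."""

    def __init__(self, records: Iterable[PedigreeRecord]):
        self._records: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.id in self._records:
                raise ValueError(f"duplicate animal id {r.id}")
            self._records[r.id] = r

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def record(self, animal_id: str) -> PedigreeRecord:
        try:
            return self._records[animal_id]
        except KeyError:
            raise KeyError(f"animal {animal_id} not in pedigree") from None

    @classmethod
    def read_tsv(cls, source) -> "PedigreeGraph":
        """Read a 5-column pedigree: id, sire, dam, breed, founder(0/1).

        "0" marks an unknown parent.
        """
        from .genotype_io import _open_text

        records = []
        with _open_text(source) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 5:
                    raise ValueError(
                        f"pedigree line {lineno}: expected 5 columns, got {len(fields)}"
                    )
                aid, sire, dam, breed, founder = fields
                records.append(PedigreeRecord(
                    aid,
                    None if sire == UNKNOWN else sire,
                    None if dam == UNKNOWN else dam,
                    breed,
                    founder == "1",
                ))
        return cls(records)

    def write_tsv(self, dest) -> None:
        from .genotype_io import _open_text

        with _open_text(dest, "w") as fh:
            for r in self._records.values():
                fh.write(
                    f"{r.id}\t{r.sire or UNKNOWN}\t{r.dam or UNKNOWN}\t"
                    f"{r.breed}\t{int(r.founder)}\n"
                )


def is_fullblood(graph: PedigreeGraph, animal_id: str, breed: str) -> bool:
    """True iff every ancestral path ends at a founder of ``breed``.

    A non-founder with an unknown parent, or any founder of another breed
    anywhere in the ancestry, disqualifies the animal regardless of the
    offending fraction.
    """
    memo: dict[str, bool] = {}
    stack: list[str] = []

    def visit(aid: str) -> bool:
        if aid in memo:
            return memo[aid]
        if aid in stack:
            raise PedigreeCycleError(stack[stack.index(aid):] + [aid])
        rec = graph.record(aid)
        if rec.founder:
            result = rec.breed == breed
        elif rec.sire is None or rec.dam is None:
            result = False  # pedigree gap, not a founder
        else:
            stack.append(aid)
            result = visit(rec.sire) and visit(rec.dam)
            stack.pop()
        memo[aid] = result
        return result

    return visit(animal_id)


def expected_composition(graph: PedigreeGraph, animal_id: str) -> dict[str, float]:
    """Pedigree-expected breed fractions (dyadic rationals summing to 1).

    Founders contribute 100% of their breed; each unknown parent
    contributes a 100% "unknown" vector; otherwise the mean of the two
    parents' vectors.  Memoized over the whole graph.
    """
    memo: dict[str, dict[str, float]] = {}
    stack: list[str] = []

    def visit(aid: str | None) -> dict[str, float]:
        if aid is None:
            return {UNKNOWN_BREED: 1.0}
        if aid in memo:
            return memo[aid]
        if aid in stack:
            raise PedigreeCycleError(stack[stack.index(aid):] + [aid])
        rec = graph.record(aid)
        if rec.founder:
            comp = {rec.breed: 1.0}
        elif rec.sire is None and rec.dam is None:
            comp = {UNKNOWN_BREED: 1.0}
        else:
            stack.append(aid)
            sire_comp = visit(rec.sire)
            dam_comp = visit(rec.dam)
            stack.pop()
            comp = {}
            for src in (sire_comp, dam_comp):
                for b, f in src.items():
                    comp[b] = comp.get(b, 0.0) + f / 2.0
        memo[aid] = comp
        return comp

    return visit(animal_id)
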