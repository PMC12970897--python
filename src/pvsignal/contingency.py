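"""2×2 contingency tables for drug × event disproportionality.

The counting unit is the report: ``a`` counts reports carrying both the
target drug (in a qualifying suspect role) and the target event,
``b`` reports with the drug but other events, ``c`` reports with the
event under other drugs, and ``d`` the remainder of the database.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .dataset import SRSDataset, select_reports

__all__ = ["ContingencyTable", "DegenerateTableError", "build_table"]


class DegenerateTableError(ValueError):
    """Raised when a margin needed by the disproportionality statistics is 0."""


@dataclass(frozen=True)
class ContingencyTable:
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"cell {name} negative: {v}")
        if self.n_total <= 0:
            raise ValueError("empty table")

    @property
    def n(self) -> float:
        """Case count for the pair (the a cell)."""
        return self.a

    @property
    def n_exposed(self) -> float:
        return self.a + self.b

    @property
    def n_event(self) -> float:
        return self.a + self.c

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "ContingencyTable":
        """Haldane–Anscombe continuity correction: add 0.5 to every cell."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    def transpose(self) -> "ContingencyTable":
        """Swap the drug and event axes (b and c)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


def build_table(
    ds: SRSDataset,
    ingredients: Iterable[str],
    event_pts: Iterable[str] | None = None,
    roles: Iterable[str] | None = None,
) -> ContingencyTable:
    """Report-level 2×2 table for a drug(-set) × event-PT query.

    Cells come from the exposure/event report sets; ``N`` is the number of
    deduplicated reports in the database. Raises
    :class:`DegenerateTableError` when either margin is empty.
    """
    exposed, with_event, both = select_reports(ds, ingredients, roles, event_pts)
    a = len(both)
    b = len(exposed) - a
    c = len(with_event) - a
    d = ds.n_reports - a - b - c
    if a + b == 0:
        raise DegenerateTableError("no exposed reports for the drug query")
    if a + c == 0:
        raise DegenerateTableError("no reports with the target event")
    return ContingencyTable(a, b, c, d)
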