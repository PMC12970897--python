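"""Rebuild a full 2×2 table from published screening-table marginals.

Published disproportionality tables print the case count ``a``, the
exposed-report and event-report margins, and the ROR point estimate, but
not the background cell ``d``. Because ROR = ad/(bc) is monotone in d,
the full table is recoverable by inverting the printed ROR:

    d = ROR · b · c / a,   with b = n_exposed − a, c = n_event − a.

All other statistics (PRR, χ², E, RR, IC) then follow from the
reconstructed table, which allows a published analysis to be checked —
or reproduced — without access to the raw database extract.
"""

from __future__ import annotations

from .contingency import ContingencyTable

__all__ = ["table_from_marginals", "SCREENING_ROW_MARGINALS"]


def table_from_marginals(a: float, n_exposed: float, n_event: float, ror: float) -> ContingencyTable:
    """Invert a printed ROR for the background cell and return the table."""
    b = n_exposed - a
    c = n_event - a
    if min(a, b, c) <= 0:
        raise ValueError("need a > 0 and both margins strictly greater than a")
    if ror <= 0:
        raise ValueError("ROR must be positive")
    d = ror * b * c / a
    return ContingencyTable(a, b, c, d)


#: Printed marginals of the three whole-class / whole-drug screening rows
#: that reconstruct consistently: (a, exposed reports, event reports,
#: printed ROR point estimate).
SCREENING_ROW_MARGINALS: dict[str, dict[str, float]] = {
    "FAERS_LTRA": {"a": 822, "n_exposed": 104_037, "n_event": 2_509, "ror": 268.58},
    "JADER_LTRA": {"a": 150, "n_exposed": 1_948, "n_event": 466, "ror": 449.22},
    "CVAR_montelukast": {"a": 61, "n_exposed": 37_404, "n_event": 237, "ror": 40.81},
}
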