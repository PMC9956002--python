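"""Packaged reference data: the published site × substrate time table.

The packaged table lists, for the haloalkane dehalogenase LinB study system,
the cumulative interaction time (ns) of seven substrates with nine transient
binding sites on the enzyme surface.  Site 1 is the entrance of the main
substrate tunnel (p1) and is excluded from key-site selection in the
reference workflow.  Substrate column codes: 1CH = 1-chlorohexane,
1BB = 1-bromobutane, 1IP = 1-iodopropane, 12DBE = 1,2-dibromoethane,
12DBP = 1,2-dibromopropane, BCH = bromocyclohexane, CCP = chlorocyclopentane.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["SUBSTRATES", "P1_SITE_ID", "load_table1_fixture", "table_column"]

SUBSTRATES = ("1CH", "1BB", "1IP", "12DBE", "12DBP", "BCH", "CCP")

#: Site id of the main-tunnel (p1) entrance in the packaged table.
P1_SITE_ID = 1


def load_table1_fixture() -> pd.DataFrame:
    """Site × substrate interaction times (ns); NaN marks absent pairs."""
    resource = files("tbsmap").joinpath("data/table1.tsv")
    with resource.open("r", encoding="utf-8") as handle:
        frame = pd.read_csv(handle, sep="\t", index_col="site", na_values="-")
    return frame


def table_column(frame: pd.DataFrame, substrate: str) -> dict[int, float]:
    """One substrate's non-absent site times as a site → ns mapping."""
    column = frame[substrate].dropna()
    return {int(site): float(value) for site, value in column.items()}
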