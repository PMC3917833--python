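"""Bundled reference tables: published 18S primers, approximate V regions."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..resolution import RegionDefinition


def _path(name: str):
    return resources.files(__package__) / name


def published_primers() -> pd.DataFrame:
    """Published universal eukaryote 18S primers with vendor Tm and %GC.

    Columns: id, sequence, orientation, published_tm_c, published_gc_percent.
    """
    with resources.as_file(_path("published_primers_18s.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def default_v_regions(include_v6: bool = False) -> list[RegionDefinition]:
    """Approximate V1-V9 coordinates on the S. cerevisiae 18S gene."""
    with resources.as_file(_path("v_regions_18s.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    regions = [
        RegionDefinition(r["name"], int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]
    if not include_v6:
        regions = [r for r in regions if r.name != "V6"]
    return regions
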