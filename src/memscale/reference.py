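"""Packaged reference data.

``anchor_depths.tsv`` holds published per-residue membrane depths
(mean ± sd, Å, from atomistic simulation) for the surface side chains of
the iPLA2 anchor region — the distance between each side chain's centre
of mass and the bilayer centre.  The rows are input data; class
summaries are always computed from them with
:func:`memscale.analysis.group_depth_summary`, never stored.
"""

from importlib import resources
import io

import pandas as pd

__all__ = ["load_anchor_depth_table"]


def load_anchor_depth_table() -> pd.DataFrame:
    """Per-residue anchor depth rows (res_id, res_name, res_class,
    mean_depth, sd_depth), compatible with
    :func:`memscale.analysis.group_depth_summary`."""
    text = resources.files("memscale.data").joinpath(
        "anchor_depths.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")
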