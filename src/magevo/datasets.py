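"""Small bundled datasets.

``load_hmt_mag_stats`` returns the published statistics of the seven
heterotrophic marine Thaumarchaeota (HMT) MAGs — bin size, CheckM and
Rinke-marker-set completeness, and contamination — used as inputs to
genome-size extrapolation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_hmt_mag_stats() -> pd.DataFrame:
    """MAG statistics table: one row per MAG.

    Columns: ``mag_id``, ``bin_size_kbp``, ``completeness_checkm_pct``,
    ``completeness_rinke_pct``, ``contamination_pct``.
    """
    with resources.files("magevo").joinpath("data/mag_stats.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
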