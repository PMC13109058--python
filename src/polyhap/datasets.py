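"""Small bundled datasets used as worked examples.

``published_tihs_pvalues`` returns the 12 raw two-sided empirical
P-values reported by a published tiHS polygenic-adaptation scan of
metabolic and hematological traits in a Tongan panel.  They serve as a
worked example for the Benjamini-Hochberg step (the adjusted values are
recomputed, never stored).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def published_tihs_pvalues() -> pd.Series:
    """Trait -> raw empirical P mapping (ordered as published)."""
    with resources.files("polyhap.data").joinpath(
            "tihs_raw_pvalues.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return pd.Series(df["p"].to_numpy(dtype=float),
                     index=df["trait"].tolist(), name="p")
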