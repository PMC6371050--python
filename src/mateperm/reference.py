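"""Bundled reference summaries from a published 537-respondent cohort study.

Two small tables ship with the package so that cross-measure equivalence and
the cumulative-effect accumulation can be exercised on realistic 21-trait
inputs without any raw questionnaire data (which is not publicly deposited):

* ``consistency_summary()`` — per-trait observed/expected consistency index,
  relocation effect size with 95% CI, respondent-attributable variance (%)
  and double-entry Pearson r.
* ``shared_effect_reference()`` — the matching trait × trait table of simple
  effect sizes (diagonal) and pairwise shared effect sizes (lower triangle).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .shared_cumulative import SharedEffectTable


def _data_path(name: str):
    return importlib.resources.files("mateperm") / "_data" / name


def consistency_summary() -> pd.DataFrame:
    """Per-trait consistency summary for the 21 standard partner traits."""
    with importlib.resources.as_file(_data_path("consistency_summary_reference.csv")) as p:
        return pd.read_csv(p)


def shared_effect_reference() -> SharedEffectTable:
    """Simple + pairwise shared effect sizes for the 21 standard traits."""
    with importlib.resources.as_file(_data_path("shared_effects_reference.csv")) as p:
        return SharedEffectTable.from_csv(p)
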