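"""Bundled datasets.

``dhc_panel_inhibition()`` returns the in-vitro inhibition panel of ten
common dihydrochalcones (phloretin, 3-OH-phloretin, asebogenin, sieboldin,
phloridzin, trilobatin and relatives, numbered 1-10) assayed at 10 uM
against six candidate targets - aromatase (CYP19A1), 17beta-HSD2 (HSD17B2),
17beta-HSD3 (HSD17B3), AKR1C3, 5-lipoxygenase (ALOX5) and COX-1 (PTGS1) -
as percent inhibition mean +/- sd over three replicates.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from targetfish.consensus import read_assay_table


def dhc_panel_assay_path() -> Path:
    """Path of the bundled inhibition-panel CSV (compound_id,target_id,mean,sd)."""
    return Path(str(resources.files("targetfish") / "data" / "dhc_panel_assays.csv"))


def dhc_panel_inhibition() -> list[tuple[str, str, float, float]]:
    """The inhibition panel as (compound_id, target_id, mean, sd) rows."""
    return read_assay_table(dhc_panel_assay_path())
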