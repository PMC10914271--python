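"""Built-in empirical dose-response parameter sets.

Currently ships the four-genotype gefitinib seascape measured in engineered
PC9 non-small cell lung cancer lines (wild type, BRAF V600E, KRAS G12V, and
the double mutant), as four-parameter Hill curves fitted to growth rates.
"""

from __future__ import annotations

from .seascape import FitnessSeascape, HillCurve

__all__ = ["gefitinib_pc9_seascape", "GEFITINIB_MW", "GEFITINIB_NET_LOSS_UM", "gefitinib_um_to_ug_ml"]

#: molar mass of gefitinib, g/mol
GEFITINIB_MW = 446.9

#: gefitinib concentration (μM) above which cell division is fully inhibited
GEFITINIB_NET_LOSS_UM = 1.8

#: genotype bit convention: site 0 (leftmost) = BRAF V600E, site 1 = KRAS G12V
PC9_GENOTYPE_NAMES = {"00": "WT", "10": "BRAF", "01": "KRAS", "11": "BRAF-KRAS"}

# growth rates in hr^-1, IC50 in ug/mL, Hill coefficient dimensionless
_PC9_PARAMS = {
    "00": HillCurve(g_max=0.039, g_min=0.018, ic50=0.033, nu=2.18),  # WT
    "10": HillCurve(g_max=0.037, g_min=0.029, ic50=0.037, nu=2.19),  # BRAF
    "01": HillCurve(g_max=0.036, g_min=0.033, ic50=0.020, nu=17.45),  # KRAS
    "11": HillCurve(g_max=0.035, g_min=0.029, ic50=0.053, nu=1.85),  # BRAF-KRAS
}


def gefitinib_pc9_seascape() -> FitnessSeascape:
    """Empirical PC9/gefitinib fitness seascape (four Hill curves, μg/mL axis)."""
    return FitnessSeascape(dict(_PC9_PARAMS), concentration_unit="ug/mL")


def gefitinib_um_to_ug_ml(conc_um: float) -> float:
    """Convert a gefitinib concentration from μM to μg/mL."""
    return conc_um * GEFITINIB_MW / 1000.0
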