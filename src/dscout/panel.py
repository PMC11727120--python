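"""Marker panel: dye channels x chip regions -> the six CTC markers.

The assay runs two physical regions of the digital PCR chip from the same
lysate: a *protein* region, where antibody-conjugated oligo tags report
surface-protein abundance (immuno-PCR), and an *mrna* region reporting
reverse-transcribed transcripts. Each region is read in three dye channels
(FAM, VIC, CY5), giving six markers in total.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = ("FAM", "VIC", "CY5")
REGIONS: tuple[str, ...] = ("protein", "mrna")

#: (region, channel) -> marker name
DEFAULT_PANEL: dict[tuple[str, str], str] = {
    ("protein", "FAM"): "EpCAM_protein",
    ("protein", "VIC"): "GPC3_protein",
    ("protein", "CY5"): "ASGPR_protein",
    ("mrna", "FAM"): "EpCAM_mRNA",
    ("mrna", "VIC"): "GPC3_mRNA",
    ("mrna", "CY5"): "PDL1_mRNA",
}

#: canonical marker order used by cohort matrices and scoring
MARKERS: tuple[str, ...] = (
    "EpCAM_protein",
    "GPC3_protein",
    "ASGPR_protein",
    "EpCAM_mRNA",
    "GPC3_mRNA",
    "PDL1_mRNA",
)

PROTEIN_MARKERS: tuple[str, ...] = MARKERS[:3]
MRNA_MARKERS: tuple[str, ...] = MARKERS[3:]


def marker_for(region: str, channel: str) -> str:
    """Look up the marker measured in ``region`` x ``channel``."""
    try:
        return DEFAULT_PANEL[(region, channel)]
    except KeyError:
        raise KeyError(f"no marker mapped for region={region!r}, channel={channel!r}") from None
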