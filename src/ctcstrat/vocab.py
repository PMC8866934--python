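"""Fixed vocabulary of per-cell image features and per-patient statistics.

The DEPArray CellBrowser export carries, for every sorted cell, four
morphology parameters and three intensity parameters measured on a
brightfield image and four fluorescence channels (DAPI nuclear stain,
FITC epithelial markers, PE mesenchymal markers, APC leukocyte CD45).
Background-subtracted mean intensity exists only for the fluorescence
channels, giving 4x5 + 2x5 + 4 = 34 features per cell.
"""

from __future__ import annotations

from enum import Enum

CHANNELS: tuple[str, ...] = ("brightfield", "dapi", "fitc", "pe", "apc")
FLUOR_CHANNELS: tuple[str, ...] = ("dapi", "fitc", "pe", "apc")

MORPHOLOGY_PARAMS: tuple[str, ...] = ("circularity", "circularityOV", "diameter", "perimeter")
INTENSITY_PARAMS: tuple[str, ...] = ("mean_intensity", "max_intensity")
BGSUB_PARAM: str = "mean_intensity_bgsub"

#: The 34 per-cell feature names, `<parameter>_<channel>`.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{p}_{c}" for p in MORPHOLOGY_PARAMS for c in CHANNELS]
    + [f"{p}_{c}" for p in INTENSITY_PARAMS for c in CHANNELS]
    + [f"{BGSUB_PARAM}_{c}" for c in FLUOR_CHANNELS]
)

#: Per-patient descriptive statistics computed over the cells of one class.
STATISTICS: tuple[str, ...] = ("mean", "SD", "25th", "median", "75th")

#: Per-patient cell-count features appended to the aggregated statistics.
COUNT_COLUMNS: tuple[str, ...] = (
    "total_cells",
    "n_eCTC",
    "n_CD45pos",
    "pct_eCTC",
    "pct_CD45pos",
)


class CellClass(str, Enum):
    """Phenotypic class assigned by DEPArray marker gating (taken as input)."""

    ECTC = "eCTC"
    CD45POS = "CD45pos"
    OTHER = "other"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def statistic_columns(prefix: str = "") -> list[str]:
    """All 170 aggregated column names ``<feature>_<statistic>``, optionally prefixed."""
    return [f"{prefix}{f}_{s}" for f in FEATURE_NAMES for s in STATISTICS]
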