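"""Metric-name registry for BCL2-family PPI profiles.

A profile holds 22 assay readouts per sample, one per registry name.
Three assay modalities appear in the names:

``LV``
    total level of a surface-immobilised bait protein (occupied plus
    unoccupied pools).
``CPX``
    count of a specific bait-partner protein complex, e.g. ``BCL2-BAX CPX``.
``PBA``
    probe-binding assay: a fluorescent BH3-domain probe counts the
    *unoccupied* bait pool.

Most metrics are single-molecule spot counts. Three weakly expressed
complexes (``BCLxL-BAX``, ``BCLxL-BAK``, ``BCL2-BAK``) are read out as
integrated fluorescence intensity instead, and carry a different floor
for the log2 transform (see :mod:`smpc.model`).
"""

from __future__ import annotations

#: The 22 metric names, in canonical column order.
METRIC_REGISTRY: tuple[str, ...] = (
    # total levels of the three anti-apoptotic baits and the two pore formers
    "BCL2 LV",
    "BCLxL LV",
    "MCL1 LV",
    "BAX LV",
    "BAK LV",
    # active-conformer (alpha-1-helix exposed) pools
    "active BAX LV",
    "active BAK LV",
    # bait-partner complex counts
    "BCL2-BIM CPX",
    "BCL2-BAX CPX",
    "BCL2-BAK CPX",
    "BCL2-BAD CPX",
    "BCLxL-BIM CPX",
    "BCLxL-BAX CPX",
    "BCLxL-BAK CPX",
    "MCL1-BIM CPX",
    "MCL1-BAX CPX",
    "MCL1-BAK CPX",
    "BAX-BAK CPX",
    # probe-binding assays (unoccupied bait pools)
    "BCL2-BIM_BH3 PBA",
    "BCL2-BAD PBA",
    "BCLxL-BIM_BH3 PBA",
    "MCL1-BIM_BH3 PBA",
)

#: Metrics quantified as integrated fluorescence intensity (a.u.), not spots.
INTENSITY_METRICS: frozenset[str] = frozenset(
    {"BCLxL-BAX CPX", "BCLxL-BAK CPX", "BCL2-BAK CPX"}
)

#: Floor applied to count metrics before the log2 transform (spots).
COUNT_FLOOR: float = 100.0

#: Floor applied to intensity metrics before the log2 transform (a.u.).
INTENSITY_FLOOR: float = 1e7

#: Panel selected for the BCL2 inhibitor (ABT-199) efficacy model:
#: two driver metrics and one resistance metric (negative coefficient).
ABT199_PANEL: tuple[str, ...] = (
    "BCL2-BIM_BH3 PBA",
    "BCL2-BAX CPX",
    "BCLxL-BAK CPX",
)

#: Panel selected for the MCL1 inhibitor (AZD-5991) efficacy model.
AZD5991_PANEL: tuple[str, ...] = (
    "MCL1 LV",
    "BCLxL-BIM_BH3 PBA",
    "BCLxL-BAK CPX",
)

#: Responsiveness threshold on the ex vivo AUC / estimated-score scale.
RESPONSE_THRESHOLD: float = 0.61


def validate_metric_names(names) -> None:
    """Raise ``ValueError`` if any name is not in the registry."""
    unknown = [n for n in names if n not in METRIC_REGISTRY]
    if unknown:
        raise ValueError(f"unknown metric name(s): {unknown!r}")
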