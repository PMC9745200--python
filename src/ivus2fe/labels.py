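"""Integer tissue labels shared across the pipeline.

The label values are the canonical encoding of the five VH tissue classes
plus the perivascular sleeve; 0 is reserved for background (lumen and
outside-the-vessel pixels).
"""

from __future__ import annotations

from enum import IntEnum


class Tissue(IntEnum):
    BACKGROUND = 0
    WALL = 1        # arterial wall (media/adventitia, grey in VH)
    FIBROUS = 2     # fibrotic tissue, dark green
    FIBROFATTY = 3  # light green
    NECROTIC = 4    # necrotic core, red
    CALCIUM = 5     # dense calcium, white
    SLEEVE = 6      # artificial perivascular support layer


#: Labels that count as tissue (everything except background).
TISSUE_LABELS = tuple(t for t in Tissue if t is not Tissue.BACKGROUND)

#: Human-readable names used in reports.
TISSUE_NAMES = {
    Tissue.BACKGROUND: "background",
    Tissue.WALL: "arterial_wall",
    Tissue.FIBROUS: "fibrotic",
    Tissue.FIBROFATTY: "fibrofatty",
    Tissue.NECROTIC: "necrotic_core",
    Tissue.CALCIUM: "calcium",
    Tissue.SLEEVE: "sleeve",
}
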