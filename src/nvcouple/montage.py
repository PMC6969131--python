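"""EEG montage: 31 electrodes on classical 10-20 / 10-10 positions.

Neonatal caps in this design place at least 31 electrodes on the classical
10-20 points, with intermediates added according to head circumference; the
canonical montage here is that 31-label core.  The 2-D coordinates are
approximate azimuthal-equidistant projections (vertex at the origin, +y
anterior, +x right, head rim at radius ~0.8) and feed only the synthetic
topographies and map interpolation — no statistic consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: label -> (x, y); left-right mirror symmetric.
_POSITIONS_31 = {
    "Fp1": (-0.25, 0.76), "Fpz": (0.0, 0.80), "Fp2": (0.25, 0.76),
    "F7": (-0.65, 0.47), "F3": (-0.33, 0.41), "Fz": (0.0, 0.40),
    "F4": (0.33, 0.41), "F8": (0.65, 0.47),
    "FC5": (-0.55, 0.22), "FC1": (-0.18, 0.20), "FCz": (0.0, 0.20),
    "FC2": (0.18, 0.20), "FC6": (0.55, 0.22),
    "T7": (-0.80, 0.0), "C3": (-0.40, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0), "T8": (0.80, 0.0),
    "CP5": (-0.55, -0.22), "CP1": (-0.18, -0.20), "CPz": (0.0, -0.20),
    "CP2": (0.18, -0.20), "CP6": (0.55, -0.22),
    "P7": (-0.65, -0.47), "P3": (-0.33, -0.41), "Pz": (0.0, -0.40),
    "P4": (0.33, -0.41), "P8": (0.65, -0.47),
    "O1": (-0.25, -0.76), "Oz": (0.0, -0.80), "O2": (0.25, -0.76),
}

LABELS_31 = tuple(_POSITIONS_31)


@dataclass
class Montage:
    """Electrode labels with projected 2-D coordinates (unit head radius)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 2)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def default_montage() -> Montage:
    """The canonical 31-electrode montage."""
    return Montage(
        labels=LABELS_31,
        positions=np.asarray([_POSITIONS_31[lab] for lab in LABELS_31], float),
    )
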