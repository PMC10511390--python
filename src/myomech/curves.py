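"""Stress-strain curve container and delimited-text I/O.

A curve holds paired nominal strain / nominal stress samples for one
compression test (simulated or experimental).  Nominal strain is
``eps = u / h0`` (platen displacement over undeformed height), the loading
stretch is ``lambda = 1 - eps``, and stress is the nominal loading-direction
stress in kPa, negative in compression.

Curves serialize to CSV with the header ``strain,stretch,stress_kPa`` plus an
optional JSON sidecar (``<file>.meta.json``) carrying protocol metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["StressStrainCurve"]

_CSV_COLUMNS = ["strain", "stretch", "stress_kPa"]


@dataclass
class StressStrainCurve:
    """Paired nominal strain / stress samples with protocol metadata.

    Attributes
    ----------
    strain : ndarray
        Nominal strains, strictly increasing, starting at 0 for full curves.
    stress : ndarray
        Nominal loading-direction stress in kPa (negative in compression).
    protocol : str
        Protocol name, e.g. ``"axial_45"`` or ``"semiconfined_II"``.
    specimen : str or None
        Specimen identifier for experimental/synthetic replicates.
    meta : dict
        Free-form provenance (seed, parameters, package version, ...);
        serialized with the curve, so keep it JSON-safe.
    extras : dict
        Non-serialized diagnostics (solver volume ratios, free dofs, ...).
    """

    strain: np.ndarray
    stress: np.ndarray
    protocol: str = ""
    specimen: str | None = None
    meta: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float).ravel()
        self.stress = np.asarray(self.stress, dtype=float).ravel()
        if self.strain.size != self.stress.size:
            raise ValueError("strain and stress must have the same length")
        if self.strain.size == 0:
            raise ValueError("empty curve")
        if self.strain.size > 1 and not np.all(np.diff(self.strain) > 0):
            raise ValueError("strain samples must be strictly increasing")
        if not (np.all(np.isfinite(self.strain)) and np.all(np.isfinite(self.stress))):
            raise ValueError("curve contains non-finite values")

    @property
    def stretch(self) -> np.ndarray:
        """Loading-direction stretch, lambda = 1 - strain."""
        return 1.0 - self.strain

    @property
    def max_strain(self) -> float:
        return float(self.strain[-1])

    def __len__(self) -> int:
        return self.strain.size

    # ---- I/O -----------------------------------------------------------

    def to_csv(self, path, sidecar: bool = True) -> Path:
        """Write ``strain,stretch,stress_kPa`` CSV (+ metadata sidecar JSON)."""
        path = Path(path)
        df = pd.DataFrame(
            {"strain": self.strain, "stretch": self.stretch, "stress_kPa": self.stress}
        )
        df.to_csv(path, index=False, float_format="%.10g")
        if sidecar:
            meta = dict(self.meta)
            meta.update({"protocol": self.protocol, "specimen": self.specimen})
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=1, sort_keys=True)
            )
        return path

    @classmethod
    def from_csv(
        cls, path, protocol: str | None = None, specimen: str | None = None
    ) -> "StressStrainCurve":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in ("strain", "stress_kPa") if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing column(s) {missing}")
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        if protocol is None:
            protocol = meta.pop("protocol", "") or ""
        else:
            meta.pop("protocol", None)
        if specimen is None:
            specimen = meta.pop("specimen", None)
        else:
            meta.pop("specimen", None)
        return cls(
            strain=df["strain"].to_numpy(),
            stress=df["stress_kPa"].to_numpy(),
            protocol=protocol,
            specimen=specimen,
            meta=meta,
        )
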