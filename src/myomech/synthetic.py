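"""Synthetic compression campaigns emulating the experimental study design.

No raw specimen curves are deposited for the rabbit soleus campaign the
model was built around, so this module generates surrogate campaigns with
the same design: six protocols (axial 0/45/90 and semi-confined modes
I/II/III), the published replicate counts (12/16/14 and 14/15/15, 86 tests
in total), 40% maximum nominal strain in 50 load steps, and an
exponential compressive stress-strain shape produced by the forward model
itself.

Variability has two documented components:

* an inter-specimen stiffness scale: each replicate's ``c1`` is multiplied
  by a mean-one lognormal draw (default sigma 0.2), mimicking
  animal-to-animal stiffness spread;
* heteroscedastic measurement noise: multiplicative Gaussian noise whose SD
  grows linearly from zero at zero strain to a fraction of the local mean
  (default 0.25) at maximum compression, so the largest scatter sits at the
  largest stress — as reported for the real campaign, where the maximum
  SD stays below ~44% of the mean.

The reference stress at zero strain is forced to exactly zero.  All
randomness flows through one seeded generator; campaigns are reproducible
bit for bit from their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constitutive import MaterialParameters
from .curves import StressStrainCurve
from .identify import ExperimentSet
from .solver import LoadProtocol, simulate_protocol, standard_protocols

__all__ = [
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_REPLICATES",
    "CampaignSpec",
    "generate_replicate",
    "generate_campaign",
    "write_campaign",
]

# default ground truth: the combined six-experiment identification result,
# which puts synthetic stress endpoints in the physiological kPa range
DEFAULT_TRUE_PARAMS = MaterialParameters(c1=0.39, c2=0.53, c3=1.27)

# replicate counts per protocol in the experimental campaign (total 86)
DEFAULT_REPLICATES: dict[str, int] = {
    "axial_0": 12,
    "axial_45": 16,
    "axial_90": 14,
    "semiconfined_I": 14,
    "semiconfined_II": 15,
    "semiconfined_III": 15,
}


@dataclass(frozen=True)
class CampaignSpec:
    """Design of one synthetic campaign.

    ``noise_sd_frac`` is the multiplicative stress-noise SD at maximum
    strain (it ramps linearly from zero); ``specimen_scale_sd`` is the
    lognormal sigma of the per-specimen stiffness factor.
    """

    true_params: MaterialParameters = DEFAULT_TRUE_PARAMS
    replicates: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    noise_sd_frac: float = 0.25
    specimen_scale_sd: float = 0.2
    max_nominal_strain: float = 0.40
    n_steps: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.replicates.values()):
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd_frac < 0 or self.specimen_scale_sd < 0:
            raise ValueError("noise SD fractions must be >= 0")

    @property
    def n_total(self) -> int:
        return sum(self.replicates.values())

    def protocols(self) -> list[LoadProtocol]:
        return [
            p.replace(
                max_nominal_strain=self.max_nominal_strain, n_steps=self.n_steps
            )
            for p in standard_protocols()
            if p.name in self.replicates
        ]

    def to_dict(self) -> dict:
        return {
            "true_params": json.loads(self.true_params.to_json()),
            "replicates": dict(self.replicates),
            "noise_sd_frac": self.noise_sd_frac,
            "specimen_scale_sd": self.specimen_scale_sd,
            "max_nominal_strain": self.max_nominal_strain,
            "n_steps": self.n_steps,
            "seed": self.seed,
        }


def generate_replicate(
    protocol: LoadProtocol,
    true_params: MaterialParameters,
    specimen_scale: float,
    noise_sd_frac: float,
    rng: np.random.Generator,
    specimen: str | None = None,
) -> StressStrainCurve:
    """One synthetic specimen curve for a protocol.

    The forward model is run with ``c1`` scaled by the specimen stiffness
    factor, then multiplicative Gaussian noise with SD ramping linearly from
    0 (at eps = 0) to ``noise_sd_frac`` (at maximum strain) is applied
    pointwise.  With zero noise and unit scale the replicate equals the
    noiseless simulation exactly.
    """
    if specimen_scale <= 0.0:
        raise ValueError("specimen_scale must be positive")
    params = true_params.replace(c1=true_params.c1 * specimen_scale)
    base = simulate_protocol(protocol, params)
    strain = base.strain
    if protocol.max_nominal_strain > 0 and noise_sd_frac > 0:
        ramp = strain / protocol.max_nominal_strain
        factors = 1.0 + noise_sd_frac * ramp * rng.standard_normal(strain.size)
    else:
        factors = np.ones(strain.size)
    stress = base.stress * factors
    stress[strain == 0.0] = 0.0
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        protocol=protocol.name,
        specimen=specimen,
        meta={
            "specimen_scale": float(specimen_scale),
            "noise_sd_frac": float(noise_sd_frac),
        },
    )


def generate_campaign(spec: CampaignSpec) -> ExperimentSet:
    """Generate the full multi-protocol campaign defined by ``spec``.

    Deterministic for a fixed seed.  The per-specimen stiffness scales are
    mean-one lognormal draws ``exp(sigma Z - sigma^2 / 2)``, so large
    campaigns average to the noiseless response.
    """
    rng = np.random.default_rng(spec.seed)
    sd = spec.specimen_scale_sd
    curves: dict[str, list[StressStrainCurve]] = {}
    for proto in spec.protocols():
        group = []
        for k in range(spec.replicates[proto.name]):
            scale = float(np.exp(sd * rng.standard_normal() - 0.5 * sd * sd))
            group.append(
                generate_replicate(
                    proto,
                    spec.true_params,
                    scale,
                    spec.noise_sd_frac,
                    rng,
                    specimen=f"{proto.name}_{k + 1:02d}",
                )
            )
        curves[proto.name] = group
    return ExperimentSet(curves=curves, meta={"spec": spec.to_dict()})


def write_campaign(spec: CampaignSpec, directory) -> Path:
    """Generate a campaign and write it as curve CSVs plus ``manifest.json``.

    Returns the directory path.  Written campaigns round-trip losslessly
    through :func:`myomech.identify.load_campaign` (to CSV printing
    precision).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    experiment_set = generate_campaign(spec)
    manifest: dict = {"seed": spec.seed, "spec": spec.to_dict(), "protocols": {}}
    for name, group in experiment_set.curves.items():
        files = []
        for curve in group:
            fname = f"{curve.specimen}.csv"
            curve.to_csv(directory / fname)
            files.append(fname)
        manifest["protocols"][name] = files
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return directory
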