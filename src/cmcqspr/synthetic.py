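"""Seeded generator of QSPR-structured surfactant datasets.

The experimental 488-observation CMC table behind the published correlations
is not deposited, so this module emulates its structure for testing and
demonstration: physical variables drawn uniformly from the study's observed
ranges (T 273.15-363.15 K, S_eq 0-70131.36 ppm, pH 6.146-11.133), a pool of
descriptor columns with equicorrelated Gaussian blocks (a realistic
collinearity challenge for subset selection), and a response built from a
planted sparse linear ground truth plus Gaussian noise.  The ground truth is
returned so selection and fitting can be scored against it.

The defaults reproduce the study's scale: 488 compounds, a 1410-descriptor
pool, an eight-term planted model (five descriptors + T, pH, S_eq) whose
coefficients echo the published linear correlation, and a noise level that
places the training R^2 near 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import DescriptorTable, ModelingDataset, SampleRecord

T_RANGE = (273.15, 363.15)          # K
SEQ_RANGE = (0.0, 70131.36)         # ppm NaCl-equivalent
PH_RANGE = (6.146, 11.133)

# Default planted coefficients: physical-variable terms at the published
# linear correlation's values, five descriptor terms of comparable weight
# on unit-variance descriptor columns.
_DEFAULT_PHYS_COEF = {"T": 0.002290, "pH": -0.083577, "S_eq": -0.000023}
_DEFAULT_DESC_COEF = (-0.50, -0.47, -0.45, -0.60, -0.40)
_DEFAULT_INTERCEPT = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    n_compounds: int = 488
    n_descriptors: int = 1410
    planted_subset: tuple[int, ...] = (0, 5, 10, 15, 20)
    planted_descriptor_coefficients: tuple[float, ...] = _DEFAULT_DESC_COEF
    planted_physical_coefficients: dict = field(
        default_factory=lambda: dict(_DEFAULT_PHYS_COEF))
    intercept: float = _DEFAULT_INTERCEPT
    noise_sd: float = 0.40
    descriptor_correlation: float = 0.3
    block_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if len(self.planted_subset) > self.n_descriptors:
            raise ValueError("planted subset larger than descriptor pool")
        if len(self.planted_subset) != len(self.planted_descriptor_coefficients):
            raise ValueError("one coefficient per planted descriptor required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.descriptor_correlation < 1.0:
            raise ValueError("descriptor_correlation must lie in [0, 1)")
        if max(self.planted_subset, default=-1) >= self.n_descriptors:
            raise ValueError("planted index outside the pool")


def generate_dataset(spec: SyntheticSpec) -> tuple[ModelingDataset, dict]:
    """Generate a dataset and its ground truth, reproducibly under the seed.

    Descriptor columns come in blocks of ``block_size`` sharing a common
    latent factor (equicorrelated with correlation
    ``descriptor_correlation``); blocks are mutually independent.  The
    response is

        y = intercept + sum(planted descriptor terms)
            + cT*T + cpH*pH + cSeq*S_eq + N(0, noise_sd^2).
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_descriptors
    T = rng.uniform(*T_RANGE, size=n)
    S_eq = rng.uniform(*SEQ_RANGE, size=n)
    pH = rng.uniform(*PH_RANGE, size=n)

    rho = spec.descriptor_correlation
    D = np.empty((n, p))
    for start in range(0, p, spec.block_size):
        width = min(spec.block_size, p - start)
        shared = rng.standard_normal((n, 1))
        own = rng.standard_normal((n, width))
        D[:, start:start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own

    phys = spec.planted_physical_coefficients
    y = (spec.intercept
         + phys.get("T", 0.0) * T
         + phys.get("pH", 0.0) * pH
         + phys.get("S_eq", 0.0) * S_eq)
    for j, c in zip(spec.planted_subset, spec.planted_descriptor_coefficients):
        y = y + c * D[:, j]
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=n)

    ids = [f"C{i+1:04d}" for i in range(n)]
    names = [f"D{j+1:04d}" for j in range(p)]
    records = [
        SampleRecord(compound_id=ids[i], T=float(T[i]), pH=float(pH[i]),
                     S_eq=float(S_eq[i]), log_cmc=float(y[i]))
        for i in range(n)
    ]
    dataset = ModelingDataset(
        records=records,
        descriptors=DescriptorTable(ids, names, D),
    )
    truth = {
        "planted_descriptors": [names[j] for j in spec.planted_subset],
        "planted_indices": list(spec.planted_subset),
        "descriptor_coefficients": list(spec.planted_descriptor_coefficients),
        "physical_coefficients": dict(phys),
        "intercept": spec.intercept,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }
    return dataset, truth


def sds_fixture():
    """The packaged sodium dodecyl sulfate worked example.

    Returns (record, descriptors, expected) where *expected* holds the
    published experimental log10(CMC) and the three model estimates printed
    for this compound.
    """
    from .published import SurfactantDescriptorSet

    record = SampleRecord(
        compound_id="sodium dodecyl sulfate",
        T=298.15, pH=7.0, S_eq=309.75, log_cmc=0.805,
    )
    desc = SurfactantDescriptorSet(
        Lop=2.911, CIC2=2.838, EEig12x=0.0, BEHp2=3.574, G3s=0.275,
    )
    expected = {
        "log_cmc_exp": 0.805,
        "log_cmc_linear": 0.516,
        "log_cmc_gp": 0.729,
        "log_cmc_sgb": 0.804,
    }
    return record, desc, expected
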