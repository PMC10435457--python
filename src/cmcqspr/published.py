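"""Fixed-coefficient evaluators of published CMC correlations.

Three correlations are shipped:

* the classical Klevens homologue relation log10(CMC) = A - B*N, where N
  is the carbon count of the surfactant tail;
* the eight-variable linear brine correlation (temperature, pH,
  NaCl-equivalent salinity plus five molecular descriptors of the
  surfactant anion), shipped as a versioned JSON model document;
* the genetic-programming closed form for the same variables.

The printed GP formula contains two typographically ambiguous junctions,
so :func:`gp_cmc_2023` exposes named *readings* and reports a per-term
breakdown; see ``GP_READINGS`` for the exact formula of each reading.
Neither reading reproduces the single printed worked-example value, which
is why the reading is an explicit argument and the breakdown is returned
for inspection rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

from .dataset import SampleRecord
from .mlr import LinearQsprModel, predict_linear


@dataclass(frozen=True)
class SurfactantDescriptorSet:
    """The five selected anion descriptors.

    Lop: lopping centric index (topological).
    CIC2: complementary information content, 2nd-order neighborhood symmetry.
    EEig12x: eigenvalue 12 of the edge adjacency matrix weighted by edge degrees.
    BEHp2: Burden-matrix eigenvalue 2 weighted by atomic polarizabilities.
    G3s: 3rd-component symmetry directional WHIM index weighted by
         electro-topological states.
    """

    Lop: float
    CIC2: float
    EEig12x: float
    BEHp2: float
    G3s: float

    def __post_init__(self):
        for f in ("Lop", "CIC2", "EEig12x", "BEHp2", "G3s"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"descriptor {f} must be finite")


@dataclass(frozen=True)
class KlevensParams:
    A: float
    B: float
    N: int

    def __post_init__(self):
        if self.N < 0 or int(self.N) != self.N:
            raise ValueError("N must be a nonnegative integer")


def klevens_log_cmc(params: KlevensParams) -> float:
    """Homologue-series relation log10(CMC) = A - B*N."""
    return params.A - params.B * params.N


def load_linear_2023() -> LinearQsprModel:
    """Load the published eight-variable linear model from packaged JSON."""
    text = resources.files("cmcqspr.data").joinpath("linear_cmc_2023.json").read_text()
    return LinearQsprModel.from_json(text)


def linear_cmc_2023(record: SampleRecord, desc: SurfactantDescriptorSet) -> float:
    """Evaluate the published linear brine correlation in double precision."""
    model = load_linear_2023()
    row = [[record.T, record.pH, record.S_eq,
            desc.CIC2, desc.EEig12x, desc.Lop, desc.BEHp2, desc.G3s]]
    return float(predict_linear(model, row)[0])


GP_READINGS = {
    "as_typeset": (
        "product junction: the (BEHp2+G3s)(0.0001654*S_eq + 31.68*(CIC2+EEig12x)"
        "/(1.407*T+2.815*S_eq)) bracket multiplies 0.01423*EEig12x*(pH+G3s)/G3s, "
        "exactly as the terms abut on the printed line; the trailing '- +0.4997' "
        "is read as '+0.4997'."
    ),
    "subtractive": (
        "subtraction junction: -(BEHp2+G3s)(0.0001654*S_eq + 31.68*(CIC2+EEig12x)"
        "/(1.407*T+2.815*S_eq)) and -0.01423*EEig12x*(pH+G3s)/G3s enter as two "
        "separate terms; the trailing '- +0.4997' is read as '-0.4997'."
    ),
}


def gp_cmc_2023(record: SampleRecord, desc: SurfactantDescriptorSet,
                reading: str = "as_typeset", return_terms: bool = False):
    """Evaluate the published GP closed form under a named operator reading.

    Requires G3s != 0 and pH != 0 (both appear as denominators) and the two
    temperature/salinity combinations to be nonzero.  With
    ``return_terms=True`` the per-term breakdown is returned alongside the
    total so the two readings can be compared term by term.
    """
    if reading not in GP_READINGS:
        raise ValueError(f"unknown reading {reading!r}; choose from {sorted(GP_READINGS)}")
    T, pH, Seq = record.T, record.pH, record.S_eq
    Lop, CIC2, E, BEHp2, G3s = desc.Lop, desc.CIC2, desc.EEig12x, desc.BEHp2, desc.G3s
    if G3s == 0:
        raise ZeroDivisionError("G3s = 0: the (pH + G3s)/G3s term is undefined")
    if pH == 0:
        raise ZeroDivisionError("pH = 0: the (1 - 1/pH) term is undefined")
    if 1.407 * T + 2.815 * Seq == 0:
        raise ZeroDivisionError("1.407*T + 2.815*S_eq = 0 denominator")
    if T + Seq == 0:
        raise ZeroDivisionError("T + S_eq = 0 denominator")

    terms = {
        "seq_linear": 0.0006095 * Seq,
        "cic2_linear": -13.76 * CIC2,
        "eeig_linear": 0.0003308 * E,
        "behp2_linear": -6.882 * BEHp2,
        "eeig_sq": 0.001219 * E ** 2,
        "double_exp": -1.096 * (math.exp(-E * (E + G3s)) + math.exp(-2.0 * E ** 2)),
        "exp_exp": 13.56 * math.exp(-math.exp(G3s - CIC2)),
        "ratio_seq": -3.961 * (CIC2 + E) * ((Seq - 9.438) / (9.007 * (T + Seq))),
        "cic2_block": 0.8278 * (CIC2 - math.exp(-CIC2))
                      * (CIC2 * (1.0 - 1.0 / pH) + 9.447),
        "lop_exp": -0.5913 * (2.908 * Lop - CIC2) * math.exp(BEHp2 - 5.068),
        "constant": 26.1,
    }
    bracket = 0.0001654 * Seq + 31.68 * ((CIC2 + E) / (1.407 * T + 2.815 * Seq))
    eeig_ph = 0.01423 * E * ((pH + G3s) / G3s)
    tail = 0.4997 * math.exp(2.0 * E - CIC2)
    if reading == "as_typeset":
        terms["junction"] = -(BEHp2 + G3s) * bracket * eeig_ph
        terms["tail_exp"] = +tail
    else:
        terms["junction"] = -(BEHp2 + G3s) * bracket
        terms["junction_eeig"] = -eeig_ph
        terms["tail_exp"] = -tail
    total = sum(terms.values())
    if not math.isfinite(total):
        raise ZeroDivisionError("non-finite value in GP correlation evaluation")
    if return_terms:
        return total, terms
    return total
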