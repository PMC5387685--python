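"""Drug-likeness and toxicity-risk rule engine.

Implements the classical multi-property filters used in library profiling:

* Lipinski's rule of 5 (RO5), reported as a full violation count 0-4 with the
  violated properties named (the rule is conventionally considered violated
  at two or more broken criteria);
* the Golden Triangle in the (log D at pH 7, MW) plane, a region associated
  with favorable permeability and low clearance (boundary inclusive);
* the Pfizer 3/75 rule (elevated in-vivo toxicity risk when logP > 3 and
  TPSA < 75, strict inequalities);
* CNS-likeness cutoffs (MW <= 450, TPSA <= 80, HBA <= 5, inclusive);
* QED, the weighted geometric mean of eight desirability-transformed
  properties, with the published asymmetric-double-sigmoid parameters and
  weights shipped as a versioned data file.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import minimize_scalar

from .descriptors import DescriptorVector

logger = logging.getLogger(__name__)

__all__ = [
    "RuleReport",
    "ro5",
    "ro5_pair_frequencies",
    "golden_triangle",
    "pfizer_3_75",
    "cns_like",
    "qed",
    "qed_from_properties",
    "QEDModel",
    "load_qed_model",
    "evaluate_rules",
    "GOLDEN_TRIANGLE_VERTICES",
]

RO5_CUTOFFS = {"MW": 500.0, "logP": 5.0, "HBA": 10.0, "HBD": 5.0}

# (logD, MW) vertices: baseline from logD -2 to 5 at MW 200, apex at MW 450.
GOLDEN_TRIANGLE_VERTICES = ((-2.0, 200.0), (5.0, 200.0), (1.5, 450.0))

QED_FLOOR = 1e-6


@dataclass
class RuleReport:
    """Per-compound outcomes of the rule engine."""

    ro5_violations: int
    ro5_violated_props: frozenset[str]
    ro5_compliant: bool          # <= 1 violation (conventional reading)
    golden_triangle: bool
    pfizer_3_75_risk: bool
    cns_like: bool
    qed: float


def ro5(dv: DescriptorVector) -> tuple[int, frozenset[str]]:
    """Rule-of-5 violation count and the set of violated properties.

    Criteria: MW <= 500, logP <= 5, HBA (N+O) <= 10, HBD (OH+NH) <= 5;
    one violation per criterion broken (strict >).
    """
    values = {"MW": dv.mw, "logP": dv.logp, "HBA": dv.hba, "HBD": dv.hbd}
    violated = frozenset(k for k, cutoff in RO5_CUTOFFS.items() if values[k] > cutoff)
    return len(violated), violated


def ro5_pair_frequencies(
    violated_sets: list[frozenset[str]],
) -> list[tuple[tuple[str, str], float]]:
    """Ranked descriptor-pair frequencies among multi-violation compounds.

    Considers only reports with >= 2 violations; a report with k violations
    contributes all C(k, 2) unordered pairs. Frequencies are normalized by
    the number of >= 2-violation reports (so they may sum above 1).
    """
    if not violated_sets:
        raise ValueError("ro5_pair_frequencies requires at least one report")
    multi = [s for s in violated_sets if len(s) >= 2]
    if not multi:
        return []
    counts: Counter[tuple[str, str]] = Counter()
    for s in multi:
        for pair in itertools.combinations(sorted(s), 2):
            counts[pair] += 1
    n = len(multi)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(pair, c / n) for pair, c in ranked]


def golden_triangle(dv: DescriptorVector) -> bool:
    """Point-in-triangle test in the (logD at pH 7, MW) plane, boundary
    inclusive. MW below the 200 Da baseline is outside."""
    mw, logd = dv.mw, dv.logd_ph7
    (lo_d, base_mw), (hi_d, _), (apex_d, apex_mw) = GOLDEN_TRIANGLE_VERTICES
    if mw < base_mw or mw > apex_mw:
        return False
    t = (mw - base_mw) / (apex_mw - base_mw)
    left = lo_d + (apex_d - lo_d) * t
    right = hi_d + (apex_d - hi_d) * t
    return left <= logd <= right


def pfizer_3_75(dv: DescriptorVector) -> bool:
    """True iff logP > 3 and TPSA < 75 (the elevated-toxicity-risk region;
    strict inequalities)."""
    return dv.logp > 3.0 and dv.tpsa < 75.0


def cns_like(dv: DescriptorVector) -> bool:
    """True iff MW <= 450, TPSA <= 80 and HBA <= 5 (inclusive cutoffs)."""
    return dv.mw <= 450.0 and dv.tpsa <= 80.0 and dv.hba <= 5.0


# --------------------------------------------------------------------------
# QED


def _ads(x: float, a: float, b: float, c: float, d: float, e: float, f: float) -> float:
    """Asymmetric double sigmoid."""
    return a + b / (1.0 + math.exp(-(x - c + d / 2.0) / e)) * (
        1.0 - 1.0 / (1.0 + math.exp(-(x - c - d / 2.0) / f))
    )


class QEDModel:
    """QED desirability model: eight ADS functions plus a weight vector.

    Each desirability is normalized by its numerically located maximum so the
    best attainable per-property score is exactly 1.
    """

    PROPERTIES = (
        "mw",
        "logp",
        "hba",
        "hbd",
        "tpsa",
        "rotatable_bonds",
        "aromatic_rings",
        "alerts",
    )

    def __init__(self, ads_params: dict[str, dict[str, float]], weights: dict[str, float]):
        self.ads_params = ads_params
        self.weights = dict(weights)
        self._argmax: dict[str, float] = {}
        self._dmax: dict[str, float] = {}
        for prop in self.PROPERTIES:
            p = ads_params[prop]
            xmax, dmax = self._locate_max(p)
            self._argmax[prop] = xmax
            self._dmax[prop] = dmax

    @staticmethod
    def _locate_max(p: dict[str, float]) -> tuple[float, float]:
        xs = np.linspace(-20.0, 1500.0, 8000)
        ys = [_ads(x, **p) for x in xs]
        i = int(np.argmax(ys))
        lo, hi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
        res = minimize_scalar(lambda x: -_ads(x, **p), bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-12})
        return float(res.x), float(-res.fun)

    def argmax_vector(self) -> dict[str, float]:
        """The property vector at which every desirability (hence QED) is 1."""
        return dict(self._argmax)

    def desirability(self, prop: str, x: float) -> float:
        p = self.ads_params[prop]
        return _ads(x, **p) / self._dmax[prop]

    def qed(self, properties: dict[str, float]) -> float:
        """Weighted geometric mean of the normalized desirabilities, in (0, 1]."""
        total_w = 0.0
        acc = 0.0
        for prop in self.PROPERTIES:
            w = self.weights[prop]
            d = self.desirability(prop, properties[prop])
            if d <= 0.0:
                logger.warning("QED desirability for %s clamped to floor", prop)
                d = QED_FLOOR
            d = min(d, 1.0)
            acc += w * math.log(d)
            total_w += w
        return math.exp(acc / total_w)


_MODEL_CACHE: dict[str, QEDModel] = {}


def load_qed_model(weight_set: str = "mean") -> QEDModel:
    """Load the shipped QED parameterization with one of the published weight
    sets ('mean' — the weighted-QED default, 'max', or 'unit')."""
    if weight_set not in _MODEL_CACHE:
        data = json.loads(
            resources.files("chemprofiler.data").joinpath("qed_params.json").read_text()
        )
        if weight_set not in data["weights"]:
            raise ValueError(
                f"unknown weight set {weight_set!r}; available: {sorted(data['weights'])}"
            )
        _MODEL_CACHE[weight_set] = QEDModel(data["ads"], data["weights"][weight_set])
    return _MODEL_CACHE[weight_set]


def qed_from_properties(properties: dict[str, float], weight_set: str = "mean") -> float:
    return load_qed_model(weight_set).qed(properties)


def qed(dv: DescriptorVector, alert_count: int, weight_set: str = "mean") -> float:
    """QED for one compound, using the package's uniform HBA (N+O) and HBD
    (OH+NH) conventions and the structural-alert count from the alerts
    module."""
    props = {
        "mw": dv.mw,
        "logp": dv.logp,
        "hba": float(dv.hba),
        "hbd": float(dv.hbd),
        "tpsa": dv.tpsa,
        "rotatable_bonds": float(dv.rotatable_bonds),
        "aromatic_rings": float(dv.aromatic_rings),
        "alerts": float(alert_count),
    }
    return qed_from_properties(props, weight_set=weight_set)


def evaluate_rules(dv: DescriptorVector, alert_count: int = 0) -> RuleReport:
    """Run every rule for one compound and bundle the outcomes."""
    n_viol, violated = ro5(dv)
    return RuleReport(
        ro5_violations=n_viol,
        ro5_violated_props=violated,
        ro5_compliant=n_viol <= 1,
        golden_triangle=golden_triangle(dv),
        pfizer_3_75_risk=pfizer_3_75(dv),
        cns_like=cns_like(dv),
        qed=qed(dv, alert_count),
    )
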