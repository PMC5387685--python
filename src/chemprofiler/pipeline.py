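"""End-to-end profiling: records -> one tidy per-compound table.

Chains descriptor computation, alert screening and the rule engine so the
comparative layer (and the CLI) can work from a single DataFrame.
"""

from __future__ import annotations

import pandas as pd

from .alerts import load_catalog, phospholipidosis_flag, screen_set
from .curation import CompoundRecord
from .descriptors import compute_descriptors
from .rules import evaluate_rules

__all__ = ["profile_set"]


def profile_set(records: list[CompoundRecord]) -> pd.DataFrame:
    """Full per-compound profile: descriptors, alert counts, rule outcomes.

    Returns one row per compound, indexed in input order, with stable column
    order — reprofiling the same records yields a byte-identical CSV.
    """
    pains = load_catalog("pains")
    sa = load_catalog("structural_alerts")
    reports = screen_set(records, [pains, sa])

    rows = []
    for rec in records:
        dv = compute_descriptors(rec)
        rep = reports[rec.id]
        rules = evaluate_rules(dv, alert_count=rep.alert_count)
        pld, pld_pattern = phospholipidosis_flag(rec, dv)
        row = {"id": rec.id, "dataset": rec.dataset, "smiles": rec.smiles}
        row.update(dv.as_dict())
        row.update(
            {
                "pains_families": ";".join(sorted(rep.families("pains"))),
                "alert_families": ";".join(sorted(rep.families("structural_alerts"))),
                "alert_count": rep.alert_count,
                "has_pains": bool(rep.families("pains")),
                "phospholipidosis": pld,
                "phospholipidosis_pattern": pld_pattern or "",
                "ro5_violations": rules.ro5_violations,
                "ro5_violated_props": ";".join(sorted(rules.ro5_violated_props)),
                "ro5_compliant": rules.ro5_compliant,
                "golden_triangle": rules.golden_triangle,
                "pfizer_3_75_risk": rules.pfizer_3_75_risk,
                "cns_like": rules.cns_like,
                "qed": rules.qed,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
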