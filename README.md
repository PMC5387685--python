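# chemprofiler

Physicochemical and rule-based ADMET profiling of compound sets.

Early drug-discovery triage asks the same questions of every compound
collection — protein–protein-interaction inhibitor libraries most acutely,
since those compounds tend to be large, lipophilic and aromatic: how do the
sets compare on MW, logP/logD, TPSA, hydrogen bonding, flexibility,
aromaticity, Fsp³ and solubility? How many pass the classical drug-likeness
rules? Which carry assay-interference or toxicophore substructures?
`chemprofiler` packages that analysis as a tested library and CLI:

* **curation** — SMILES/SDF reading, salt stripping (largest covalent
  fragment), inclusive MW windowing (default 150–900 Da), sphere-exclusion
  diversity selection on FCFP-style circular fingerprints (Tanimoto ≤ 0.2)
  with a seeded 650-compound cap;
* **descriptors** — the full panel plus a rule-based pH-7 ionization model
  (logD, formal charges), an ESOL-style logS, and a topological **shape
  index** (longest shortest heavy-atom chain, atom count with both ends
  included, over heavy-atom count) for (logP, logS, shape) BDDCS-style maps;
* **rules** — Lipinski RO5 with full 0–4 violation counts and violated-pair
  statistics, the Golden Triangle in the (logD, MW) plane (baseline logD
  −2…5 at 200 Da, apex at 450 Da, boundary inclusive), the Pfizer 3/75
  toxicity-risk rule (logP > 3 and TPSA < 75, strict), CNS-likeness
  (MW ≤ 450, TPSA ≤ 80, HBA ≤ 5), and **QED** — the weighted geometric mean
  of eight desirability-transformed properties, QED =
  exp(Σ wᵢ ln dᵢ / Σ wᵢ), with the published ADS parameters shipped as data;
* **alerts** — SMARTS catalogs for PAINS families and structural alerts
  (toxicophores), plus a cationic-amphiphilic-drug phospholipidosis flag;
* **stats** — Table-style summaries (Mdn / M / SEM / P95), Welch confidence
  intervals and p-values for mean differences between sets, Gaussian KDE
  curves, threshold categorization;
* **synthetic_data** — a hand-verifiable fixture panel with an
  oracle-derived expected-value table, and a seeded grammar-based generator
  producing compound sets with controlled MW/logP/ionization structure, so
  everything is testable without external downloads.

## Worked example

```python
from chemprofiler import records_from_smiles, compute_descriptors, evaluate_rules
from chemprofiler.alerts import load_catalog, screen

recs = records_from_smiles([
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("Oc1ccccc1O", "catechol"),
    ("CN(C)CCCc1ccc(-c2ccccc2)cc1", "amphiphile"),
])
sa, pains = load_catalog("structural_alerts"), load_catalog("pains")
for rec in recs:
    dv = compute_descriptors(rec)
    rules = evaluate_rules(dv, alert_count=screen(rec, sa).alert_count)
    print(f"{rec.id}: MW={dv.mw:.2f} logP={dv.logp:.2f} logD={dv.logd_ph7:.2f} "
          f"TPSA={dv.tpsa:.1f} HBD={dv.hbd} HBA={dv.hba} shape={dv.shape_index:.3f} "
          f"logS={dv.logs:.2f}")
    print(f"  RO5 violations={rules.ro5_violations} GT={rules.golden_triangle} "
          f"3/75={rules.pfizer_3_75_risk} CNS={rules.cns_like} QED={rules.qed:.3f} "
          f"PAINS={screen(rec, pains).families('pains')}")
```

prints

```
aspirin: MW=180.16 logP=1.31 logD=-1.49 TPSA=63.6 HBD=1 HBA=4 shape=0.538 logS=-1.93
  RO5 violations=0 GT=False 3/75=False CNS=True QED=0.761 PAINS=[]
catechol: MW=110.11 logP=1.10 logD=1.10 TPSA=40.5 HBD=2 HBA=2 shape=0.625 logS=-1.77
  RO5 violations=0 GT=False 3/75=False CNS=True QED=0.525 PAINS=['catechol_A']
amphiphile: MW=239.36 logP=3.85 logD=1.35 TPSA=3.2 HBD=0 HBA=1 shape=0.722 logS=-3.91
  RO5 violations=0 GT=True 3/75=True CNS=True QED=0.766 PAINS=[]
```

Reading it: aspirin's carboxylic acid is deprotonated at pH 7, so logD drops
2.8 units below logP; catechol is flagged by the `catechol_A` PAINS family;
the biphenyl-propylamine is a cationic amphiphile — lipophilic (logP 3.85,
TPSA 3.2) and inside both the Golden Triangle and the 3/75 risk region.

The same pipeline runs from the shell:

```sh
profiler synth --spec spec.yaml --out set.smi
profiler curate --in set.smi --mw-min 150 --mw-max 900 --tanimoto 0.2 --cap 650 --seed 1 --out curated.smi
profiler rules --in curated.smi --out profile.csv
profiler compare --in profile.csv --groupby dataset --descriptor mw --out table.csv --pairwise-out pairs.csv
```

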