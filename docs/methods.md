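# Methods

`chemprofiler` profiles compound sets along the physicochemical and
rule-based ADMET axes used to triage screening libraries: descriptor panels,
drug-likeness rules, substructure alerts, and comparative statistics between
labelled sets. This note records the models implemented, the conventions and
parameter choices where the field offers more than one, and what the
synthetic generator does and does not emulate.

## Curation

Input sets (`.smi` or SDF V2000) are parsed with RDKit; unparseable entries
are logged and skipped, with an error raised if the file is empty or more
than half of the entries fail (a wrong-format heuristic). Salt stripping
keeps the largest covalent fragment by heavy-atom count (first fragment on
ties); charged forms as drawn are preserved and no neutralization or
tautomer canonicalization is attempted, so formal-charge counting sees the
structures as input. The molecular-weight window (default 150–900 Da,
inclusive) mirrors common screening-library bounds.

Diversity selection is sphere exclusion (leader clustering) on 2048-bit
radius-2 circular fingerprints with pharmacophoric ("feature") atom
invariants — the open analogue of functional-class FCFP4 fingerprints. A
record is kept iff its Tanimoto similarity to every previously kept record
is at most the threshold (default 0.2); input-file order defines the leader
pass, which makes the procedure deterministic. Whether a "maximum Tanimoto
coefficient" bounds similarity or distance is genuinely ambiguous in
practice, so `metric="distance"` is exposed; similarity is the default. If
more than `cap` (default 650) records survive, a uniform seeded subsample of
size `cap` is drawn and returned in input order.

## Descriptor panel

* **MW** — average atomic masses (RDKit).
* **logP** — Crippen atom-contribution estimate. All logP-derived outputs
  (logD, logS, 3/75 rule, QED) use this estimator uniformly, so
  reproducibility is defined against it.
* **HBD / HBA** — the Lipinski conventions: HBA is the N+O atom count; HBD
  is the count of N/O atoms bearing at least one hydrogen. These definitions
  are used everywhere, including inside QED (which originally used different
  acceptor definitions); this keeps every rule consistent with one panel.
* **TPSA** — Ertl fragment-additive topological polar surface area.
* **Rotatable bonds** — non-ring single bonds between two non-terminal heavy
  atoms, excluding amide C–N; rigid bonds = heavy-atom bonds − rotatable.
  **Flexibility** = rotatable / (rotatable + rigid) (an interpretation: the
  descriptor has no universal printed definition), 0 for bondless molecules.
* **Rings** — SSSR count; aromatic rings are SSSR rings whose atoms are all
  aromatic; max ring size is over SSSR rings (0 if acyclic).
* **Stereocenters** — assigned plus unassigned tetrahedral centers.
* **Fsp³** — sp³ carbons over all carbons; 0 when the molecule has no carbon.
* **Shape index** — over the heavy-atom bond graph, the number of atoms in
  the longest shortest-path chain (both ends included) divided by the
  heavy-atom count. Exactly 1.0 for every unbranched acyclic molecule, < 1
  for anything with a branch or ring; a single atom scores 1. Used as the
  third coordinate of the (logP, logS, shape) biopharmaceutics-class map.
* **logS** — an ESOL-style linear estimate,
  `logS = 0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP`
  with AP the aromatic heavy-atom fraction, in log10(mol/L). This is a
  deterministic closed form chosen so the solubility axis is computable
  offline; per-compound external predictions can be substituted through the
  plug-in CSV interface instead.

### Ionization at pH 7

Ionization is handled by a fixed SMARTS/pKa rule table — a deliberate,
documented simplification in place of a full pKa engine. Groups and typical
pKa values: carboxylic acid 4.2, sulfonic acid −1, tetrazole 4.9, phenol
9.9, N–H sulfonamide 10.0 (acids); aliphatic amine 9.5, aniline 4.6,
imidazole 7.0, amidine/guanidine 12.5 (bases). Substituent effects are
ignored.

* **logD(pH 7)** = logP − Σ_acids log10(1 + 10^(7−pKa)) − Σ_bases
  log10(1 + 10^(pKa−7)), one penalty per group instance. Penalties are
  nonnegative, so logD ≤ logP with equality iff no group matches.
* **Formal charges (pH 7)** counts charged *atoms* (not net charge):
  drawn charges, plus one per acid with pKa < 7 (deprotonated) and one per
  base with pKa > 7 (protonated). Imidazole (pKa 7.0) is deliberately left
  neutral at pH 7.

## Rules

* **RO5**: violations counted per criterion broken (strict >): MW > 500,
  logP > 5, HBA > 10, HBD > 5. The full 0–4 count and the violated-property
  set are reported; both the "0 violations" and the conventional
  "≤ 1 violation" (compliant) summaries are derivable, since published
  percentages are ambiguous between the two. Pair frequencies among
  ≥2-violation compounds count all C(k,2) unordered pairs per compound and
  normalize by the number of multi-violation compounds (they may sum > 1).
* **Golden Triangle**: point-in-triangle in the (logD at pH 7, MW) plane,
  vertices (−2, 200), (5, 200), (1.5, 450), boundary inclusive; MW below
  the 200 Da baseline is outside.
* **Pfizer 3/75**: elevated-risk flag iff logP > 3 *and* TPSA < 75, strict
  inequalities (the rule is printed with strict inequalities; the triangle
  is treated inclusively because its boundary is a drawn region, not a
  printed inequality).
* **CNS-likeness**: MW ≤ 450, TPSA ≤ 80, HBA ≤ 5, all inclusive.
* **QED**: weighted geometric mean of eight desirability-transformed
  properties (MW, logP, HBA, HBD, TPSA, rotatable bonds, aromatic rings,
  structural-alert count). The published asymmetric-double-sigmoid (ADS)
  parameters and the three published weight sets ship as a versioned data
  file (`data/qed_params.json`); the default is the information-weighted
  set (wQED). Each desirability is normalized by its maximum, which is
  re-located numerically (grid scan + bounded minimization, xatol 1e−12) at
  load rather than trusted from the printed table — this makes QED exactly
  1.0 at the argmax vector. Desirabilities ≤ 0 are clamped to 1e−6 and
  logged; QED is invariant under rescaling all weights by a positive
  constant. Note the HBA/HBD inputs follow this package's Lipinski
  conventions (above), a documented deviation from the original
  publication's acceptor definition.

## Alerts

Catalogs are plain-text `family<TAB>SMARTS` files: a 10-family PAINS subset
(including catechol_A, quinone_A, anil_NH_alk_B, sulfonamide_A) and a
20-family toxicophore catalog (Michael acceptors, quinones, epoxides, alkyl
halides, aldehydes, β-lactams, ...). The SMARTS are open re-encodings of the
canonical motifs; the catalogs are deliberately partial and versioned —
screening behavior, serialization round-trips, and the QED alert count
(distinct toxicophore families matched; PAINS hits excluded) are the
contract, not family-list completeness.

The phospholipidosis flag is a composite cationic-amphiphilic-drug rule:
inducer iff the compound has ≥ 1 nitrogen protonatable at pH 7 (per the
ionization table), ≥ 2 rings, and logP ≥ 3. This is a reimplementation of
the *contract* of SMARTS-fragment CAD classifiers (boolean + named matched
pattern), not any specific published fragment list.

## Statistics

Summaries report median, mean, SEM (sd with n−1 denominator over √n; 0 when
n = 1), and the 95th percentile by linear interpolation between order
statistics (the convention is stated because published tables rarely state
theirs). Mean differences use the Welch two-sample t construction by
default — the safe choice for unequal-size, unequal-variance compound
sets — with the pooled-variance variant available; zero-variance or n < 2
groups raise an error pointing at exact/permutation alternatives. Pairwise
p-values are reported unadjusted by default, with an optional Holm
correction. KDE curves use a Gaussian kernel with Silverman bandwidth.
Categorization uses half-open bins [c_i, c_{i+1}), values at a cutpoint
falling in the upper bin.

## Synthetic generator

`generate_set` assembles SMILES from a small grammar — heads, chain linkers,
ring templates (benzene/pyridine/pyrimidine/cyclohexane variants), and
terminal substituents including acid, amine, and alert-bearing (catechol,
enone, alkyl chloride, acrylonitrile) groups — and rejection-samples against
the package-computed MW and logP until each molecule lands within ±2 SD of
the targets. A per-molecule size is drawn from the target normal and the
ring count steered toward it (~115 Da per decorated ring), which keeps the
realized MW mean within a few Da of the target; an exact additive mass
(standalone piece masses minus 2.016 Da per join) screens proposals before
any parsing, and computed values are memoized per SMILES so replicated
simulations converge to cache hits. Defaults: MW (350, 50), logP (3.0, 1.2),
ionizable mix 20% acid / 30% base / 50% neutral, 10% alert rate — chosen
once as a realistic oral-drug-like profile. Everything is driven by one
seeded generator, so output (ordering included) is reproducible.

What the generator does *not* emulate: real activity data, scaffold
diversity beyond the grammar, tautomers/salts (it emits single neutral
fragments), stereochemistry, or correlations between descriptors beyond
those the grammar induces. Tests passing on synthetic sets therefore
demonstrate the correctness of the *machinery* (descriptors, rules,
statistics) under controlled conditions, not conclusions about any real
compound collection.

## Problem sizes and numerical choices

The test suite runs the statistics-recovery simulation at 1,000 null
replicates and 200 shifted replicates with n = 100 per group, and the
determinism check on a 500-compound set — sizes chosen to give tight Monte
Carlo error on the false-positive rate (±1.4% at 1,000 replicates) while the
whole suite stays in the minutes range on one CPU. Floating-point
comparisons in tests use explicit tolerances (1e−12 for graph-derived
quantities, 0.01 Da for masses); descriptor permutation-invariance is
asserted to 1e−9 to allow summation-order effects.

## Known limitations

* The pKa table is rule-based; micro-pKa shifts, zwitterion equilibria and
  tautomer-dependent ionization are out of scope.
* Crippen logP and ESOL logS are estimators; absolute values carry the
  biases of those models even though all internal comparisons are
  self-consistent.
* Alert catalogs are partial by design.
* The composite phospholipidosis rule approximates fragment-based CAD
  classifiers and should not be read as a validated toxicity model.
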