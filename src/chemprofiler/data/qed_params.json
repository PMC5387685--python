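{
  "comment": "Published asymmetric-double-sigmoid (ADS) desirability parameters and weight sets for the quantitative estimate of drug-likeness (QED). Each property desirability is ads(x; a,b,c,d,e,f) normalized by its maximum. 'mean' is the information-weighted set used for weighted QED (wQED); 'max' and 'unit' are the alternative published sets.",
  "version": 1,
  "ads": {
    "mw":     {"a": 2.817065973, "b": 392.5754953, "c": 290.7489764, "d": 2.419764353, "e": 49.22325677, "f": 65.37051707},
    "logp":   {"a": 3.172690585, "b": 137.8624751, "c": 2.534937431, "d": 4.581497897, "e": 0.822739154, "f": 0.576295591},
    "hba":    {"a": 2.948620388, "b": 160.4605972, "c": 3.615294657, "d": 4.435986202, "e": 0.290141953, "f": 1.300669958},
    "hbd":    {"a": 1.618662227, "b": 1010.051101, "c": 0.985094388, "d": 1e-09, "e": 0.713820843, "f": 0.920922555},
    "tpsa":   {"a": 1.876861559, "b": 125.2232657, "c": 62.90773554, "d": 87.83366614, "e": 12.01999824, "f": 28.51324732},
    "rotatable_bonds": {"a": 0.01, "b": 272.4121427, "c": 2.55837997, "d": 1.565547684, "e": 1.271567166, "f": 2.758063707},
    "aromatic_rings":  {"a": 3.21778897, "b": 957.7374108, "c": 2.274627939, "d": 1e-09, "e": 1.317690384, "f": 0.375760881},
    "alerts": {"a": 0.01, "b": 1199.094025, "c": -0.09002883, "d": 1e-09, "e": 0.185904477, "f": 0.875193782}
  },
  "weights": {
    "mean": {"mw": 0.66, "logp": 0.46, "hba": 0.05, "hbd": 0.61, "tpsa": 0.06, "rotatable_bonds": 0.65, "aromatic_rings": 0.48, "alerts": 0.95},
    "max":  {"mw": 0.5,  "logp": 0.25, "hba": 0.0,  "hbd": 0.5,  "tpsa": 0.0,  "rotatable_bonds": 0.5,  "aromatic_rings": 0.25, "alerts": 1.0},
    "unit": {"mw": 1.0,  "logp": 1.0,  "hba": 1.0,  "hbd": 1.0,  "tpsa": 1.0,  "rotatable_bonds": 1.0,  "aromatic_rings": 1.0,  "alerts": 1.0}
  }
}
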