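# Literature kinetic parameterization of the core liver circuit.
# Units: production 1e6 molecules / hr, degradation 1/hr, thresholds 1e6 molecules.
# Degradation rates derive from reported protein half-lives via ln(2)/t_half.
nodes:
  HNF4A: {production: 0.4540, degradation: 0.0491}
  HNF1A: {production: 0.0570, degradation: 0.0494}
  PPARG: {production: 0.0628, degradation: 0.08}
  SREBF1: {production: 1.1058, degradation: 0.1598}
edges:
- {source: HNF4A, target: HNF4A, fold_change: 4.0, cooperativity: 4, threshold: 3.0}
- {source: HNF1A, target: HNF1A, fold_change: 2.0, cooperativity: 4, threshold: 0.8}
- {source: PPARG, target: PPARG, fold_change: 9.514, cooperativity: 5, threshold: 6.32}
- {source: SREBF1, target: SREBF1, fold_change: 4.0, cooperativity: 2, threshold: 5.25}
- {source: HNF1A, target: HNF4A, fold_change: 4.0, cooperativity: 3, threshold: 0.8}
- {source: HNF4A, target: HNF1A, fold_change: 5.328, cooperativity: 4, threshold: 5.108}
- {source: SREBF1, target: PPARG, fold_change: 3.0, cooperativity: 2, threshold: 5.25}
- {source: PPARG, target: SREBF1, fold_change: 3.729, cooperativity: 2, threshold: 9.283}
- {source: SREBF1, target: HNF4A, fold_change: 0.415, cooperativity: 2, threshold: 5.0}
- {source: HNF1A, target: PPARG, fold_change: 0.68, cooperativity: 4, threshold: 0.674}
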