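# kinnet

Allosteric enzyme-kinetics inference and co-expression module-interaction
network analysis, with synthetic-data generators that carry known ground
truth.

The package serves two audiences at once. For the enzymologist: fitting
of initial rates, Michaelis–Menten curves, activation dose–response
(AC50), one-site binding isotherms (K_d), and — the centrepiece — the
linked-function coupling constant Q_ax quantifying how an allosteric
effector reshapes substrate affinity. The motivating system is pyruvate
kinase M2 (PKM2), whose substrate (PEP) affinity is coupled to
activators such as fructose 1,6-bisphosphate (FBP) and reduced
glutathione (GSH). For the computational biologist: weighted gene
co-expression networks over regional tumor/normal RNA-seq designs
(inner core IC, invasive front IF, metastasis M, matched normal),
topological-overlap module detection, a hypergeometric module–module
interaction (MMI) statistic, over-representation analysis, and paired
Wilcoxon regional contrasts.

## Models at the core

**Thermodynamic linkage.** Apparent substrate affinity at effector
concentration X:

    K_a(X) = K_ia0 (K_ix0 + X) / (K_ix0 + Q_ax X),
    v(S, X) = V_max S / (K_a(X) + S)

with K_ia0 the substrate dissociation constant at zero effector, K_ix0
the effector dissociation constant at zero substrate. The coupling
constant is the ratio of limiting affinities, Q_ax = K_a(0)/K_a(∞);
Q_ax > 1 means activation (K_a falls as effector rises).

**MMI statistic.** For modules A and B, with m co-expressed gene pairs
(adjacency weight > τ) among the n = |A||B| possible A–B pairs, and M
co-expressed among the N possible pairs between A and all other
modules' genes, the ordered-pair significance is the hypergeometric
upper tail

    p(A→B) = P(X ≥ m),  X ~ Hypergeom(N, M, n),

and an undirected edge is significant when either p(A→B) ≤ 0.05 or
p(B→A) ≤ 0.05.

See `docs/methods.md` for assumptions, parameter defaults, numerical
conventions and limitations.

## Worked example

Simulate a noisy rate grid at the GSH-like coupling parameters and
recover the coupling constant:

```python
from kinnet import KineticsSimConfig, gen_rate_grid, fit_linkage

cfg = KineticsSimConfig(
    v_max=2.0, k_ia0=1.5, k_ix0=363.0, q_ax=3.7,
    effector_grid=(0.0, 30.0, 100.0, 300.0, 1000.0, 10000.0),
    noise_cv=0.05, replicates=3, seed=42,
)
model = fit_linkage(gen_rate_grid(cfg))
print(f"Q_ax = {model.q_ax:.2f} +/- {model.se['q_ax']:.2f}")
print(f"K_a(0) = {model.ka_at_zero:.3f} mM -> K_a(inf) = {model.ka_at_saturation:.3f} mM")
```

```
Q_ax = 3.59 +/- 0.29
K_a(0) = 1.535 mM -> K_a(inf) = 0.428 mM
```

A generating truth of 3.7 comes back as 3.59 ± 0.29 from one noisy
grid: substrate affinity tightens 3.6-fold between zero and saturating
effector.

Plant six co-expression modules, couple one pair, and ask the MMI
statistic which pair interacts:

```python
import pandas as pd
from kinnet import (ExpressionSimConfig, ModuleSpec, gen_expression, preprocess,
                    adjacency, count_coexpressed_pairs, build_mmi_network)
from kinnet.coexpression import ModulePartition

cfg = ExpressionSimConfig(
    n_genes=150, n_patients=15,
    module_spec=tuple(ModuleSpec(size=25, within_cor=0.8) for _ in range(6)),
    coupling_spec=(((2, 3), 0.9),),   # couple planted modules M3 and M4
    seed=42,
)
study, truth = gen_expression(cfg)
log_mat, _ = preprocess(study)            # log2(TPM+1), 90%-zero gene filter
adj = adjacency(log_mat, power=17)
part = ModulePartition(labels=pd.Series({g: truth.modules[g] for g in log_mat.index}))
net = build_mmi_network(count_coexpressed_pairs(adj, part, tau=0.01), alpha=0.05)
print(f"{net.graph['n_mmi']} significant MMI(s) among {net.graph['n_modules']} modules")
for a, b, d in net.edges(data=True):
    print(f"  {a}-{b}: p_ab = {d['p_ab']:.3g}, p_ba = {d['p_ba']:.3g}")
```

```
1 significant MMI(s) among 6 modules
  M3-M4: p_ab = 1.68e-168, p_ba = 1.68e-168
```

Only the planted coupling survives, in both orientations. (If you run
module *detection* on this study instead of using the planted labels,
the very strongly coupled pair merges into a single 50-gene module —
the faithful reading of a 0.9 factor correlation; see the methods
note.)

A command-line layer wraps the same functions:

```sh
kinnet simulate expression --config expr.yaml --seed 5 --out data/
kinnet net-build --expr data/expression.tsv --meta data/samples.tsv --out net/
kinnet mmi --adj net/adjacency.tsv --modules net/modules.tsv --out mmi/
kinnet contrast --expr data/expression.tsv --meta data/samples.tsv \
    --modules net/modules.tsv --pairs IF:IC,IF:M --out contrast/
```

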