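# cardevol

Comparative molecular evolution of three-taxon orthologue triplets: codon
substitution models and selection tests, reciprocal-best-hit orthology,
expression-breadth and codon-usage statistics, and class-level comparative
tests — with a synthetic-data generator that plants every signal the
analysis is meant to recover.

## The problem

Two related lineages (here labelled **Ci** and **Cr**, with **At** as the
outgroup) occupy contrasting habitats and life histories.  Given coding
sequences from all three, which genes and functional classes evolve faster
in one lineage, and is that acceleration relaxed constraint or positive
selection?  The package implements the full analysis a molecular
evolutionist would run: identify orthologue triplets by reciprocal best
hits, build in-frame codon alignments (trimmed, transit-peptide-masked),
estimate lineage-specific dN/dS under maximum likelihood, test for
selection with branch, site and branch-site likelihood-ratio tests under
FDR control, and relate the rates to expression breadth (τ, organ counts,
stress persistence) and codon usage bias (Fop, GC3).

At its core is the codon substitution model with rates

    q_ij ∝ π_j · κ^[transition] · ω^[non-synonymous]

on the 61 sense codons, fitted by maximum likelihood on the fixed unrooted
tree (At, Ci, Cr).  The model zoo covers M0 (one ω), the free-ratio model
(ω per branch), two-ratio branch models, the site mixtures M1a/M2a and
M7/M8, and branch-site model A with its test-2 null; nested pairs are
compared by χ² likelihood-ratio tests (the seven tests B, B_Ci, B_Cr,
S_21, S_87, BS_Ci, BS_Cr).  See `docs/methods.md` for conventions and
assumptions.

## Worked example

Fit the free-ratio model to one simulated orthologue triplet and test the
Cr branch for positive selection:

```python
import numpy as np
from cardevol import CodonModel, ModelSpec, lrt, nested_start
from cardevol.simulate import simulate_site_class_alignment

# one gene, 300 codons, ingroup dS near 0.06, omega 0.2 everywhere
mat, _ = simulate_site_class_alignment(
    300,
    {"At": 0.30, "Ci": 0.07, "Cr": 0.07},
    [(1.0, {"At": 0.2, "Ci": 0.2, "Cr": 0.2})],
    kappa=2.0,
    pi=np.full(61, 1 / 61),
    rng=0,
)

fr = CodonModel(mat, "FR").fit(seed=0)
print(fr.summary())
print(fr.branch_rates().to_frame().round(4))

null = CodonModel(mat, ModelSpec("BSA_null", foreground="Cr")).fit(seed=0)
alt_spec = ModelSpec("BSA_alt", foreground="Cr")
alt = CodonModel(mat, alt_spec).fit(start=nested_start(alt_spec, null), seed=0)
r = lrt(null, alt, df_override=1)
print(f"BS_Cr: 2dL = {r.statistic:.3f}, df = {r.df}, P = {r.pvalue:.3f}")
```

This prints:

```
Codon substitution model FR
  codons: 300   codon freqs: F3x4
  log-likelihood: -1765.480183   free parameters: 7
  converged: True   starts: 4   nfev: 1048
  parameter estimates:
         kappa = 1.493045
      omega_At = 0.155398
      omega_Ci = 0.154078
      omega_Cr = 0.129160
          t_At = 0.286225
          t_Ci = 0.046905
          t_Cr = 0.120188
         t      dN      dS   omega
At  0.2862  0.0382  0.2458  0.1554
Ci  0.0469  0.0062  0.0404  0.1541
Cr  0.1202  0.0140  0.1085  0.1292
BS_Cr: 2dL = 0.000, df = 1, P = 1.000
```

Per branch, dN/dS equals the fitted ω exactly under the
mutational-opportunity site counting (N + S = 3L).  The branch-site test
correctly finds nothing: no sites with ω > 1 were simulated.  The ω and κ
estimates scatter around the planted 0.2 and 2.0 — a 300-codon gene at this
divergence carries few substitutions, which is why the class-level
comparisons downstream are rank-based and why recovery is asserted on means
over many genes.

For the full pipeline (orthology → alignment → models → expression → codon
usage → class statistics) from a config file:

```
cardevol init -o config.yaml          # emits all defaults
cardevol run-all -c config.yaml -o out/
cardevol report -o out/
```

With `simulate:` set in the config the pipeline generates its own inputs
and writes a ground-truth ledger next to them; with `fasta:` paths it runs
on real coding-sequence sets, and externally produced hit tables in a
tabular (outfmt-6-style) dialect can bypass the internal aligner.

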