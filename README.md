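# gennet — genetic-and-epigenetic network inference

`gennet` reconstructs the *real* genetic-and-epigenetic network (GEN)
of a cell condition from a candidate network and matched molecular
profiles.  Interaction databases report hundreds of thousands of
putative protein–protein interactions (PPIs), TF→gene regulations and
miRNA→gene repressions, most of which are false positives for any one
tissue.  Given mRNA expression, miRNA expression and DNA-methylation
beta values over the same samples, `gennet` fits per-node,
methylation-modulated regression models, prunes candidate links by
system-order detection, and compresses the surviving network to an
interpretable core.  It is written for systems biologists who want a
tested, fully reproducible implementation of this pipeline — with a
synthetic-data generator standing in for cohort downloads.

The per-node models are

* protein interactive model:
  `y_i[n] = Σ_j a_ij·y_i[n]·y_j[n] + h_i + v_i[n]` with `h_i ≥ 0`;
* gene regulatory model:
  `x_i[n] = Σ_j b_ij·y_j[n]·M_i[n] − Σ_v c_iv·x_i[n]·x_v^miR[n]·M_i[n] + M_i[n]·κ_i + ω_i[n]`
  with `κ_i, c_iv ≥ 0`,

where `M(m) = 1/(1+(m/0.5)²)` maps methylation beta values onto
[0.2, 1]: methylation attenuates TF, miRNA and polymerase binding but
never shuts it off.  Parameters are estimated by sign-constrained
least squares; the real links are those minimizing
`AIC(Δ) = log σ̂² + 2Δ/L` under forward/backward stepwise selection,
and each retained link carries a permutation p-value (B = 1000,
floored at 1/B).  Principal network projection (PNP) then takes the
SVD of the structure matrix of identified abilities, keeps the minimal
M components with cumulative eigenexpression fraction ≥ 0.85, scores
each node by its dependent score D(k) — the 2-norm of its row
projected on those components — and extracts the top 5% of proteins
with their connected genes and miRNAs as the core GEN.  Two
conditions are compared through differential expression/methylation,
basal-level (κ) shifts and common/specific core edges.

See `docs/methods.md` for the full model description, the synthetic
generator's design, and known limitations.

## Worked example

The `analysis/` scripts run a complete synthetic two-condition study
(80 genes, 12 miRNAs, 60 samples per condition, candidate network
diluted 1:1 with decoys):

```sh
python analysis/01_simulate_cohorts.py     # truth + candidate + matrices
python analysis/02_identify_networks.py    # prune candidates per condition
python analysis/03_project_core.py         # PNP -> dependent scores, cores
python analysis/04_compare_conditions.py   # differential tables, Δκ, overlap
python analysis/05_crossval_consistency.py # ten-fold selection consistency
```

Script 02 prints, for condition A:

```
condition A: retained 383 PPIs, 135 TF regulations, 46 miRNA repressions (pruned 69/491/480)
  recovery vs flagged truth on modeled sinks: precision 0.631, recall 0.986, F1 0.769
```

i.e. of the 452/626/526 candidate edges, the AIC order detection
pruned 69/491/480 and the retained network recovers essentially every
planted edge on the modeled genes (recall 0.99) at a precision
reflecting AIC's known false-positive load.  Script 03 reports the
spectral compression:

```
condition A: 21 principal components carry 85.0% of the eigenexpression; core = 4 top proteins + 36 connected genes + 0 miRNAs, 133 induced edges
```

and script 04 ties the planted epigenetic perturbation to its
readout — every shifted gene is called in the right direction with
the methylation permutation p at the 10⁻³ floor, e.g.:

```
  G0030: hyper  p_meth=0.001  p_expr=0.001  dkappa=-0.064
```

Script 05 quantifies robustness of the selection across ten-fold
resampling (63.5% of PPIN edges and 34.2% of GRN edges selected in all
ten repetitions at this desk scale).  Derived tables land in
`results/study/`; the bulky simulated matrices go to `scratch/study/`.

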