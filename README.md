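# guildnet

Hurdle latent-factor joint species distribution modelling (JSDM) of **paired
fungal and bacterial communities** — for microbial ecologists who want to know
whether two guilds sequenced from the same samples merely share habitat, or
carry information about each other beyond the environment, and in which
direction.

Given two OTU-by-sample count tables (one per guild) and sample covariates
(deadwood chemistry and physical log characteristics in the motivating
application), `guildnet`:

1. fits a **hurdle JSDM** by Gibbs sampling — every OTU enters twice, as a
   probit presence–absence column and as a lognormal
   abundance-given-presence column (absences are missing, not zero) — with
   shared sample-level latent factors across both guilds and both parts:

   occurrence: `P(y_ij > 0) = Φ(x_i β_j + η_i λ_j)`
   abundance:  `a_ij ~ N(x_i β′_j + η_i λ′_j, σ_j²)`

2. derives **residual association networks** `R = corr(ΛΛᵀ + diag)` with
   posterior sign support, and contrasts the network of a depth-only *null*
   model against the *full* environmental model: edges that disappear were
   shared habitat use, edges that remain are candidate biotic associations;
3. **partitions explained variance** per species into chemical, physical,
   and depth covariate groups versus the latent-factor random effect;
4. measures **explanatory, unconditional, and conditional predictive power**
   (AUC for occurrence, R² for abundance) under 2-fold cross-validation,
   where the conditional regime assumes the *other* guild's occurrences and
   abundances are known in the test samples. The conditional-minus-
   unconditional gain is the information value of one guild for predicting
   the other — an observational probe of interaction **directionality**.

A seeded synthetic-community generator (`simulate_community`) mirrors the
model with known ground truth, including an asymmetric scenario
(`make_asymmetric_scenario`) in which bacteria track the shared factors three
times more strongly than fungi — the signature that makes fungi a good
predictor of bacteria but not vice versa.

## Worked example

```python
import guildnet as gn
from guildnet.evaluate import CVSpec

cfg = gn.make_asymmetric_scenario(gn.SimulationConfig(
    n_samples=100, n_species_fungi=20, n_species_bacteria=20, n_factors=3, seed=42))
study = gn.simulate_community(cfg)
resp = gn.concat_hurdle_responses(
    *[gn.assemble_hurdle_response(study.tables[g]) for g in ("fungi", "bacteria")])
design = gn.build_joint_design(study.metadata, model="full")

model = gn.HurdleLatentFactorJSDM(n_factors=3, n_chains=2, n_iter=3000,
                                  n_burn=1000, thin=10, random_state=0)
model.fit(design, resp)

net = gn.compute_association_network(model, part="occurrence", support_level=0.95)
print("supported edges:", net.n_edges(), "| between guilds:", net.n_edges(between_guild=True))

vp = gn.variance_partition(model, design)
print(gn.variance_partition_summary(vp).round(3).to_string(index=False))

report = gn.evaluate_models(study.metadata, resp, models=("full",),
                            cv=CVSpec(seed=0, outer_draws=40, inner_burn=20, inner_draws=30),
                            estimator=model)
gains = gn.directionality_gain(report)
print(gains[gains.part == "occurrence"].round(3).to_string(index=False))
```

Output:

```
supported edges: 209 | between guilds: 100
   guild     component  proportion
bacteria      chemical       0.258
bacteria         depth       0.111
bacteria      physical       0.322
bacteria random_effect       0.310
   fungi      chemical       0.353
   fungi         depth       0.115
   fungi      physical       0.390
   fungi random_effect       0.141
   guild       part metric model  conditional_gain
bacteria occurrence    auc  full             0.033
   fungi occurrence    auc  full             0.011
```

Reading this: 209 species pairs keep a sign-consistent residual correlation
at 0.95 posterior support after the covariates are accounted for. The
latent-factor (random-effect) share of explained variance is much larger for
bacteria (0.31) than for fungi (0.14) — bacteria co-vary beyond their niches.
Consistently, knowing the fungal community improves held-out bacterial
occurrence prediction by 0.033 AUC points, three times the reverse gain
(0.011): the information flows mainly from fungi to bacteria, exactly the
asymmetry this simulation builds in.

## Command line

```bash
guildnet init --out run.yaml     # commented config template
guildnet run-all run.yaml        # simulate/load -> filter -> fit null+full ->
                                 # networks -> varpart -> CV -> reports
guildnet report run.yaml         # print the power table
```

Stage subcommands (`simulate`, `filter`, `fit`, `networks`, `varpart`, `cv`)
run the pipeline up to that stage; completed stages are skipped on resume
(config-hash checked). Artifacts are TSV/JSON in the output directory.

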