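# phyloresponse

Are soil bacterial responses to environmental perturbations — warming,
drought, elevated CO₂, nutrient addition — phylogenetically conserved?
`phyloresponse` implements the analysis pipeline that answers this
question from 16S OTU count tables and a phylogeny, and ships a
synthetic-study generator with planted, known conservation structure so
every stage can be validated end to end without any sequencing data.

It is aimed at microbial ecologists who have per-location
control/treatment OTU tables and want to test whether *who responds, and
in which direction* clusters on the tree of life rather than being
scattered at random.

## The statistic

For each location, each OTU gets a response ratio

```
log2fc_i = log2( mean normalized abundance in treatment plots + c )
         - log2( mean normalized abundance in control plots   + c )
```

after occupancy filtering (keep OTUs present in ≥ half the plots;
relaxed to ≥ 2 plots when fewer than 900 OTUs survive) and
median-of-ratios normalization. Only the **sign** of `log2fc` enters the
conservation test.

The consenTRAIT statistic τ_D then measures how deep in the phylogeny
the response direction is conserved. The rooted tree is traversed from
the root; the deepest nodes where **more than 90%** of the
direction-carrying descendant tips share one sign are recorded as
*consensus clades* (strictly more: 9/10 fails, 19/20 passes). A tip
covered by no consensus clade becomes a singleton whose depth is half
the patristic distance to its nearest tip. τ_D(+) and τ_D(−) are the
mean *genetic depths* (mean node-to-descendant-tip distance,
substitutions/site) of the consensus clades of each sign. Significance
comes from shuffling the direction labels among the tips 1000 times;
p is the fraction of shuffled τ_D values ≥ the observed one. A genetic
depth *d* corresponds to roughly `200·d` percent 16S sequence
dissimilarity (two tips under a node at depth *d* are ~2*d* apart), so
τ_D = 0.017–0.024 reads as 3.4–4.8% dissimilarity — about genus level.

Around this core the package provides rarefaction + Bray–Curtis +
one-factor PERMANOVA for the overall-composition test, equal-weight
averaging of OTUs present in ≥ 3 locations with a merged consenTRAIT run
(context dependence = mean per-location τ_D − merged τ_D), and per-rank
two-tailed exact binomial tests for taxonomic groups that respond
consistently.

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study:
a 128-OTU tree, response directions planted at genetic depth 0.03 with
fidelity 0.95, and four locations (80% occupancy, 10+10 plots,
negative-binomial counts):

```sh
python analysis/01_simulate_study.py
python analysis/02_community_composition.py
python analysis/03_response_ratios.py
python analysis/04_consentrait_per_location.py
python analysis/05_cross_location.py
```

which prints, among other lines:

```
study: 128 OTUs, 4 locations, 20 planted clades (mean depth 0.0322), 92 OTUs widespread (>=3 locations)
loc1: rarefied to 3980, R2=0.576, p=0.001*
loc1: tau_D(+)=0.0221 (p=0.002), tau_D(-)=0.0233 (p=0.000); ~4.5% 16S dissimilarity
responses phylogenetically conserved at 4 of 4 locations; planted mean depth was 0.0322
merged tau_D=0.0196 (p+=0.035, p-=0.000); mean individual tau_D=0.0220; delta=+0.0024 (0.47% 16S difference)
5 of 17 taxonomic groups respond consistently (two-tailed exact test, p < 0.05)
```

Read: the perturbation shifts overall composition everywhere (PERMANOVA
R² ≈ 0.5–0.7), the response direction is significantly conserved at
every location at τ_D ≈ 0.021–0.023 (estimation noise shaves the
planted 0.032 — wrong-sign tips break clades into shallow singletons),
and merging locations costs only 0.0024 of depth, i.e. the responses
are context-independent, as planted. Outputs land in `results/`.

The same stages are available as a CLI (`phyloresponse simulate`,
`respond`, `consentrait`, `merge`, `groups`, `matrix`; see
`phyloresponse --help`) and as plain library functions.

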