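# epispread

Individualized seizure-propagation modelling on brain networks: SI epidemic
dynamics on proportionally thresholded weighted connectivity matrices,
rank-pattern fitting of the network density against invasive-EEG seizure
propagation patterns, and optimization of *virtual resections* that minimize
simulated seizure spread for a given resection size.

## The problem

Epilepsy surgery removes or disconnects the brain regions believed to start
seizures, but seizure freedom is reached in only about two thirds of operated
patients. Because the effect of a resection depends on the whole brain
network, not just the removed tissue, individualized computational models are
needed to test candidate resections *in silico* before surgery.

`epispread` is aimed at researchers in network neuroscience and computational
epileptology. It treats the early phase of a seizure as an epidemic on the
patient's weighted brain network (e.g. an amplitude-envelope-correlation
matrix over the 246-ROI Brainnetome atlas, used as a surrogate for structural
connectivity).

## The model

**Spreading.** Susceptible–Infected (SI) dynamics: at each synchronous step
an infected node *i* infects a susceptible neighbour *j* with probability
β·w<sub>ij</sub>. Networks are thresholded at density θ (the fraction of
strongest links kept, unbinarized), with mean connectivity κ = θN. To compare
densities, the rate is tied to the density, βθ = 4·10⁻⁴, and propagation is
quantified by the infected fraction I(t₀) at t₀ = 50 steps.

**Fitting.** SEEG contact points are mapped to their nearest ROI centroids
and grouped into activation steps; midpoint-tie ranks give the clinical
pattern RANK<sup>SEEG</sup>. For each θ in a grid, the β → 0 slow-propagation
limit (one new node per step, chosen ∝ its total weight to the infected set)
yields mean activation orders, ranked over the same sampled ROIs as
RANK<sup>SI</sup>. The two are compared with

C = cov(RANK<sup>SEEG</sup>, RANK<sup>SI</sup>) / (σ(RANK<sup>SEEG</sup>)·σ(RANK<sup>SI</sup>)),

with a two-sided permutation p-value; the lowest-density significant maximum
of C(θ) is the patient's fitted density.

**Resections.** A virtual resection zeroes all links of the chosen nodes.
Optimal resections per size S are found by simulated annealing over the seed's
≤2-hop neighbourhood, maximizing the mean *effective distance* to the seed
(per-link length 1 − ln P<sub>ij</sub>), then refined by SI simulation.
Summaries: R90 (smallest resection with i<sub>R</sub> = I<sub>R</sub>(t₀)/I(t₀) ≤ 0.1),
R100 (zero spread beyond the seed in every run), R1 (best single node), and
the seed's link budget E<sub>RA</sub> = S<sub>RA</sub>·κ<sub>RA</sub>.

Clinical patient data are not distributable, so the `synth` module generates
synthetic patients (distance-decay networks with noise, compact seeds,
seed-biased sparse SEEG sampling, step-coarsened activation patterns) that
exercise every stage end to end.

## Worked example

Generate a synthetic patient (90 ROIs, 4-ROI seed, 30 sampled ROIs, planted
density 0.10), fit the density, and search resections:

```bash
epispread synth --n-rois 90 --seed-size 4 --n-sampled 30 --seed 7 --out demo/pat
epispread fit --network demo/pat/network.tsv --rois demo/pat/rois.tsv \
    --pattern demo/pat/pattern.tsv --seed-file demo/pat/seed.txt \
    --n-runs 1000 --seed 7 --out demo/fit
epispread resect --network demo/pat/network.tsv --rois demo/pat/rois.tsv \
    --seed-file demo/pat/seed.txt --theta 0.1 --n-runs 1000 --seed 7 --out demo/res
```

prints

```
{"theta_max": 0.1, "kappa_max": 9.0, "C_max": 0.9848374321357964, "p_max": 9.999000099990002e-05, "significant": true, "seed_kind": "RA"}
{"S_RA": 4, "kappa_RA": 9.0, "E_RA": 36.0, "baseline_extent": 0.01719767441860465, "R90_size": 4, "R90_set": [4, 9, 34, 57], "R100_size": 4, "R100_set": [4, 9, 34, 57], "s90": 1.0, "s100": 1.0, "i_R1": 0.601081812035159, "R1_node": 34}
```

The fit recovers the planted density (θ_max = 0.10, i.e. κ = 9 at N = 90)
with rank correlation C = 0.985 (permutation p < 10⁻⁴). For this patient the
smallest 90%-reduction resection equals the full 4-node seed (s90 = 1), the
optimal set includes a node outside the seed (ROI 34), and the best
single-node resection alone reduces propagation by ~40% (i_R1 = 0.60).

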