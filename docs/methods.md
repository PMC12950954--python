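# Methods

`fragsense` implements the computational side of a "binary drug" sensitiser
discovery workflow: selecting a small, non-toxic fragment that structurally
resembles both a panel of pathway inhibitors and a panel of natural
metabolites (so it may share their uptake route), and quantifying how
co-administering that fragment changes the dose-response of a cytotoxic
drug. This note records the models, conventions and design choices.

## Similarity screening

**Tanimoto coefficient.** For two fixed-length bit-vector fingerprints with
`a` and `b` set bits and `c` shared set bits, `Tc = c / (a + b - c)`. The
coefficient is implemented natively on NumPy boolean vectors (not delegated
to a toolkit), is symmetric, lies in [0, 1], equals 1 for identical
non-empty vectors, and is defined as 0 (with a warning) when both vectors
are empty, avoiding 0/0. Reported values are rounded half-up to two
decimals, the convention used for printed "Tc ratio" tables.

**Fingerprint schemes.** Four standard schemes are supported, all generated
by RDKit:

| identifier | length | family |
|---|---|---|
| `structural-keys-166` | 167 | public 166-key structural keys |
| `path-based` | 2048 | hashed linear/branched paths |
| `circular-r2` | 2048 | circular environments, radius 2 |
| `substructure-pattern` | 1024 | substructure-screening pattern keys |

The reference tables this package reproduces do not name their fingerprint,
so `calibrate_scheme` scores every supported scheme by its maximum absolute
deviation from a set of known (printed) Tc values after 2-dp rounding and
selects the minimiser (ties broken by name). On the packaged ten-pair
calibration set the `substructure-pattern` scheme at 1024 bits reproduces
all ten printed values exactly (maximum deviation 0.00); the other three
schemes deviate by 0.39-0.58. The pattern scheme was added to the supported
set precisely because calibration singles it out; the package default for
uncalibrated use remains `structural-keys-166`.

**Rule of 3.** Fragment-library compliance uses the community convention
with inclusive boundaries: MW <= 300 g/mol, cLogP <= 3, H-bond donors <= 3,
acceptors <= 3, rotatable bonds <= 3, TPSA <= 60 A^2; each criterion is
individually configurable or disableable. Donor/acceptor counts use the
heavy-atom convention of the rule-based screening literature (donor = N or O
bearing at least one H, acceptor = any N or O), so water counts one donor
and one acceptor. Weight, cLogP, rotatable bonds and TPSA are the RDKit
definitions. The filter reports *every* violated criterion, and screening
applies it before ranking by default (mirroring a pre-filtered commercial
fragment library); `apply_ro3=False` disables it.

**Dual-panel selection.** A candidate sensitiser must resemble members of
both panels: its best Tc against each panel must reach that panel's
threshold (defaults 0.5/0.5, a common minimum-similarity convention), and
qualifying fragments are ranked by the *minimum* of the two best-Tc values.
Every selected hit carries MCS evidence against both best references.

## Maximum common substructure

The MCS is exact, not heuristic, and is computed natively. Molecules are
heavy-atom graphs; atoms match on element plus aromaticity (charges ignored
by default so a zwitterionic aromatic N can match a neutral one), bonds
match on exact order with aromatic matching aromatic (an any-order
relaxation is available). The maximum common **induced** subgraph is found
as a maximum clique of the modular product graph: product vertices pair
compatible atoms, and two vertices are adjacent when their atom pairs are
either both bonded with compatible orders or both non-bonded. Vertices
sharing an atom of either parent are never adjacent, which keeps every
clique an injective mapping.

By default the common subgraph must be connected (the use case is a single
shared scaffold); during branch-and-bound a clique may only grow through
product vertices joined to it by a bonded-bonded edge, in the manner of
Koch's connected-clique enumeration. The search is deterministic: vertices
are scanned in canonical order, all co-optimal cliques up to a configurable
cap are collected, ties among equal-sized mappings are broken by larger
bond count and then by lexicographically smallest mapping. Product graphs
above a configurable vertex limit (default 4000) raise a size-limit error
rather than running unbounded; the intended inputs are fragment-sized
molecules. Every result is rendered as a SMARTS pattern (atomic number +
bond order/aromaticity constraints) and verified post hoc to
substructure-match both parents.

The test suite checks the clique search against exhaustive enumeration of
all connected common induced subgraphs (ESU subset enumeration plus
label-preserving induced-subgraph isomorphism) on all pairs of a
twelve-molecule, <= 12-heavy-atom fixture set.

## Co-administration analysis

**Normalisation.** Plates are long-form CSV (`cell_line, drug_a_uM,
sensitiser_uM, replicate, signal`). Replicates are aggregated first (mean,
SEM), then every cell is expressed as percent of the untreated-control mean,
which is exactly 100%; SEMs are divided by the control mean. Normalisation
is scale-invariant by construction. Optional blank subtraction is off by
default.

**Enhancement.** `enhancement_delta(v, a, b) = viability(a, 0) -
viability(a, b)` in percentage points; positive means sensitisation.
Negative values (antagonism) are reported, never clipped, and the delta at
`b = 0` is exactly 0.

**Dose-sparing.** For a target viability bracketed by both the drug-alone
column and the combination column, each column is inverted by piecewise
linear interpolation of viability against log10(dose) (dose grids are
geometric; the 0-dose anchor is excluded), using the single monotone segment
containing the target. The sparing fraction is `1 - D_combo / D_alone`. A
target outside a column's range raises an error naming the achievable
interval; more than one crossing raises an error advising hormesis
inspection.

**Hormesis.** A column is flagged biphasic when any higher dose's mean
viability exceeds any lower dose's mean by more than `k` times the pooled
SEM `sqrt(sem_lo^2 + sem_hi^2)` (default `k = 2`); all offending dose pairs
are returned. Note that this is a per-pair evidence rule, not a family-wise
calibrated test: on an 8-point curve it scans 28 ordered pairs, so its
false-positive rate on pure noise is far above the per-pair ~2% (about 50%
at 4 replicates) regardless of the noise scale, because the threshold and
the noise share the same SEM units. Treat a flag as a prompt to inspect the
column, not as a significance statement; a family-wise-calibrated `k` would
need to grow with the number of pairs.

**Group comparison.** One-way ANOVA (SciPy) with Tukey HSD adjusted pairwise
p-values (statsmodels), starred at 0.05/0.01/0.001/0.0001. All-identical
input degenerates to F = 0, p = 1 rather than 0/0.

## Synthetic data

**Fragment libraries.** Molecules are assembled from packaged scaffold and
substituent template pools (small heterocycles decorated with 0-2 small
substituents for the compliant class; long lipophilic chains or polar-group
overload for the non-compliant class). Each molecule's class is drawn
Bernoulli(`frac_ro3`) and verified against the actual filter, with
resampling, so the realised pass fraction is exactly binomial. Everything is
deterministic under the seed.

**Viability plates.** The drug-alone curve is Hill inhibition,
`v(g) = e0 - emax * g^h / (g^h + ec50^h)`; the sensitiser contributes no
intrinsic toxicity and acts purely as a potency shift, multiplying the EC50
by `s(b) = 1 / (1 + rho * b / (b + kb))`, so the implied true dose-sparing
at sensitiser dose `b` is `1 - s(b)`. Hormesis is modelled as an additive
viability bump at the top drug dose. Replicate noise is Gaussian with sd
`noise_sd` percentage points, one seeded generator per plate.

Default parameters emulate a 96-h gemcitabine exposure of a pancreatic
carcinoma line on the 7 x 3 co-administration grid (0.003-3 uM drug in
half-decade steps; 3/10/30 uM sensitiser; controls at 0): `e0 = 100`,
`emax = 85` (a resistant plateau remains), `ec50 = 0.05 uM`, `hill = 1.8`,
`rho = 0.117` with `kb = 1 uM` (about 10% sparing at saturating sensitiser),
`noise_sd = 3`, `n_reps = 4`. These defaults were fixed from the experiment
design and typical published potencies, not fitted to any test outcome.

What the simulator does *not* emulate: plate-position and edge effects,
heteroscedastic or multiplicative assay noise, day-to-day control drift,
sensitiser toxicity at high dose, and receptor-level mechanisms. Passing
recovery tests on these plates therefore demonstrates estimator behaviour
under idealised noise, not performance on real assay data.

## Known limitations and honest failure modes

Two stated recovery goals are not attainable under the prescribed estimator
and study conditions, and their acceptance tests are intentionally left
failing rather than weakened:

* **Dose-sparing precision.** With 3% replicate noise, 4 replicates and a
  half-decade dose grid, the single-segment log-linear inversion propagates
  a per-column log-dose error of >= ~0.015 decades; combining two columns
  gives a sparing error sd of ~0.04 and a median absolute error of ~0.03
  (measured: 0.0297 over 200 plates), above the 0.02 goal. The estimator is
  also biased by up to ~0.02 when the EC50 coincides with a grid point.
  Reaching 0.02 would need roughly twice the replicates, half the noise, or
  a model-based (Hill-fit) inversion, which is out of scope here.
* **Hormesis false-positive rate.** As explained above, the per-pair k = 2
  rule cannot keep the family-wise false-positive rate of an 8-dose column
  at or below 10% (measured: 0.52 on 1000 null plates); its power for a
  15-point terminal bump is ~1.0.

Other limitations: SMILES/SDF V2000 only (no 3D, tautomers or protonation
modelling); exact MCS is exponential in the worst case and guarded only by
the vertex limit; the pattern-fingerprint calibration result is specific to
the packaged reference panels.
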