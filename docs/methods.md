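# Methods

This note documents the models and procedures implemented in `idrisle`,
the defaults that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic study system

The package analyses data it can also generate, so every stage is
testable end to end without external downloads. The generator emulates
three things.

**Genome sets.** Each genome is a single contig of protein-coding genes
(default 60) drawn from a shared background family pool (1.5× the genome
size, per-genome inclusion probability 0.7, so in- and out-groups overlap
substantially). In-group genomes additionally carry the four-gene island
contiguously on one strand, in reading-direction order marker → partner →
peroxidase₁ → peroxidase₂ (when the island lands on the minus strand the
genes are laid down in reverse coordinate order so the transcriptional
order is preserved). Decoy genomes carry an arsenite-oxidase-like locus:
a marker homolog at 55 % identity plus the partner family, with no
peroxidases. One repair pass over the background inclusion matrix swaps
any background family that would by chance occur in every in-group genome
and no out-group genome (about four such families would otherwise be
expected at the default sizes); this guarantees the in-group-unique set
is exactly the planted island, which is the ground truth the recovery
tests assert.

**Protein families.** Evolution is substitution-only. Members of a
family are mutated independently from a common ancestor at exactly the
number of positions that makes the expected member-to-member identity hit
the target: a position survives in one copy with probability (1−d) and
two mutated copies coincide with probability 1/19, giving expected
identity 1 − 2d + (20/19)d², solved for d. Families default to 90 %
identity (marker length 800 aa, accessory genes 150–350 aa). The absence
of indels keeps family members alignable column-to-column, so the profile
model needs no multiple-alignment engine; this is the one deliberate
departure from real protein evolution and means the tests say nothing
about indel robustness.

**Metagenome samples and metadata.** Each sample has a depth zone
(surface/mixed/DCM/mesopelagic, default probabilities 0.10/0.10/0.30/0.50),
a zone-dependent depth, and ten geochemical variables under their
standard survey column names. Oxygen and nitrate are drawn first from a
two-regime mixture (oxygen-depleted vs oxygenated water, with the
low-oxygen regime more likely at depth), which plants the oxygen–nitrate
anticorrelation of real ocean profiles in the table itself. Marker
presence is then Bernoulli with logistic probability
`sigmoid(−1.0 − 2.5·z(O₂) + 1.0·z(NO₃))`, and the remaining variables are
drawn conditional on presence from per-group means/SDs (present-group
oxygen 65 ± 35 vs absent-group 190 ± 45 µmol/kg, and correspondingly
deeper, colder, nutrient-richer, darker present-group samples). This
two-stage scheme resolves the circularity of specifying both a presence
model and presence-conditional variable distributions: two variables
drive presence, the other eight echo it. Positive samples receive 1–3
full-length (≥ 280 aa) marker-derived ORFs at 95 % identity to a family
member; ORF read counts are negative-binomial (dispersion 5, mean ∝
length × abundance) with marker abundance scaled by 1/oxygen so that
cumulative marker TPM rises as oxygen falls. Background ORFs are 100–500
aa (the size distribution of real ORF catalogs is not standardized; this
range brackets typical prokaryotic gene fragments). Metadata cells are
masked missing-completely-at-random (default rate 0.10, never leaving a
column with fewer than two observations); imputation is therefore tested
for mechanism recovery under MCAR, not for MNAR robustness.

Everything is driven by one integer seed; identical seeds give
byte-identical outputs, and all planted truth (island genomes, gene
families, marker-positive samples, masked cell values) is returned beside
the data.

## Clustering and island discovery

Pairwise similarity is exact Smith–Waterman (BLOSUM62, gap open 11 /
extend 1 — standard database-search defaults). Significance is a
Karlin–Altschul expect value computed from the raw score with the gapped
BLOSUM62 parameters (λ = 0.267, K = 0.041) against the total residue
count of the protein set, so the 10⁻³ edge cutoff behaves like a search
E-value. Coverage is required bidirectionally (both query and target
≥ 0.5); single-sided coverage is the laxer dialect and is not used. The
network build screens pairs with a score-only alignment first and runs
the traceback (needed only for identity and coverage) when the score
alone could clear the significance cutoff; this changes nothing about
which edges exist.

Greedy set cover repeatedly takes the uncovered node whose closed
neighborhood contains the most uncovered nodes (ties to the
lexicographically smallest id), emits it with its uncovered neighbors as
one subfamily, and repeats; the result partitions the protein set. The
presence/absence matrix is boolean per genome × subfamily regardless of
copy number, and the island candidates are the subfamilies present in all
in-group and no out-group genomes ("all" rather than "any" on the
in-group side: with the substitution-only families each subfamily is
single-copy per genome, so gene and subfamily counts coincide).

## Synteny and calibration

Neighborhoods span up to ten genes each side of the focal locus on its
contig, truncated at contig ends and orientation-normalized so the focal
strand reads left to right. Classification uses the whole window by
default: requiring the peroxidases within ±10 genes rather than strictly
adjacent is the conservative reading of "adjacent" when no gene distance
is stated; a strict mode (`max_offset=2`) is available. Neighborhood
frequency is genomes-possessing / genomes-surveyed.

The marker profile is an ungapped position-specific scoring matrix
rather than a full profile HMM: the synthetic families are indel-free, so
insert/delete states have nothing to model, and the quantity of interest
is a thresholded bit score, which the PSSM reproduces structurally.
Column probabilities are (count + α·q)/(n + α) with pseudocount α = 1 and
uniform background q = 0.05; log-odds are base-2 and floored at −20 bits
where both count and pseudocount vanish. A query's score is the best
ungapped placement (the shorter of profile and sequence sliding fully
inside the longer), which tolerates ORF fragments longer than the 280-aa
fragment filter; `X` scores zero per column. Published absolute HMM
thresholds live on a different score scale and do not transfer to the
PSSM; what transfers is the calibration *rule*: the threshold is set to
`max(score over genomes whose marker neighborhood lacks the peroxidase
pair) + δ` (δ = 1 bit), degenerating to the minimum adjacent score when
no non-adjacent genome exists, with adjacent genomes falling below
threshold reported as collateral exclusions.

## Survey and niche statistics

TPM is normalized over each sample's **whole** ORF catalog, not over the
marker hits — the standard definition, flagged in the survey output
metadata because hit-only normalization is a possible alternative reading.
Per-sample cumulative marker TPM is the sum over hits; zone fractions are
hits-in-zone over total hits. Read alignment itself is out of scope; the
pipeline consumes per-ORF counts.

MICE is deterministic by design: missing cells start at column means,
columns are cycled in fixed order, each is regressed by OLS on all others
over its originally-observed rows, and its missing cells are overwritten
with predictions until the largest cell change is below 10⁻⁶ (max 20
sweeps). Observed cells are never altered, and complete data pass through
unchanged. This is regression-prediction MICE, not the Bayesian variant
with posterior draws: determinism makes the imputation exactly
reproducible and testable, at the cost of understating imputation
uncertainty.

PCA standardizes columns to zero mean and unit variance first — the ten
variables mix metres, °C, PSU and µmol/kg, so covariance PCA would be
dominated by depth — and fixes the sign indeterminacy by orienting each
loading column so its largest-magnitude entry is positive. All samples
enter the PCA regardless of marker presence; presence labels (absent /
single hit / multiple hits) only group the outputs. Group summaries use
t-based 95 % CIs (degenerate at n = 1); ellipses are 1-SD covariance
ellipses (semi-axes = square roots of the 2×2 group covariance
eigenvalues, angle from the leading eigenvector), requiring ≥ 3 samples
per group.

## Stoichiometry and energetics

The theoretical acceptor:donor ratio for acetate oxidation on iodate is
4/3 (8 electrons per acetate, 6 per iodate, 24 per formula unit).
Assimilated acetate is ΔOD₆₀₀ × 0.39 g CDW L⁻¹ OD⁻¹ × 0.5 g C/g CDW ÷
12.011 g mol⁻¹ ÷ 2 C per acetate × 1000 (mM); using 12.000 for carbon
changes the assimilated fraction by < 0.1 %. Percent-of-theoretical is
Δiodate / (respired × 4/3) × 100 and therefore *rises* with ΔOD (more
biomass → less respired acetate → smaller theoretical demand).

ΔG per electron is −F(E_acceptor − E_donor) with F = 96.485 kJ V⁻¹
mol⁻¹. The iodate/iodide couple is taken at seawater pH (0.72 V at pH
8.1); the acetate/CO₂ donor couple defaults to the standard transformed
−0.29 V and is exposed as a parameter, since references typically print
only the resulting ΔG. With these defaults the iodate yield (−97.45
kJ/mol e⁻) lands between aerobic respiration (−107.10) and
denitrification, as the redox ladder requires.

The disproportionation ledger treats each recycling turn as
instantaneous and complete: all current iodate is reduced enzymatically
to HIO (4 e⁻ each), the HIO disproportionates to ⅔ iodide + ⅓ iodate, and
the regenerated iodate re-enters until the pool falls below tolerance
(10⁻⁹). The geometric series Σ(1/3)ᵏ = 3/2 gives the closed form —
turnovers 1.5 n₀, electrons 6 n₀, iodide n₀ — against which the iteration
is tested; kinetics of the abiotic step are out of scope.

## Pipeline and problem sizes

The orchestrated pipeline runs simulate → cluster → compare →
neighborhoods → profile/calibrate → survey → niche → energetics, writes
TSV/JSON artifacts at fixed precision with a manifest, and is
byte-deterministic for a fixed config. The analysis stages never consult
the planted truth: the marker subfamily is recognized as the
in-group-unique subfamily with the longest proteins, and the partner and
peroxidase subfamilies by position beside the focal locus in in-group
neighborhoods.

Default problem sizes — 5 genomes × 60 genes (≈ 45 000 protein pairs),
40 samples × 300 ORFs, and 200-sample/100-replicate niche checks with
reduced ORF catalogs (the niche statistic depends only on presence and
the metadata table) — were chosen so the full analysis re-runs in a few
minutes on one CPU while keeping every recovery check nontrivial.

## Known limitations

No indels, so coverage filters and fragment handling are only lightly
stressed; MCAR missingness only; the expect-value surrogate is asymptotic
and approximate for very short sequences (edges additionally require 50 %
coverage, which short spurious alignments fail); the decoy models a
single alternative neighborhood structure rather than the full diversity
of arsenite-oxidase loci; and passing recovery tests on this generator
demonstrates correctness of the inference chain, not performance on real
genomes or ocean metagenomes.
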