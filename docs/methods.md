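# Methods

This note documents the models, parameters and design choices behind
`acquisim`, in the spirit of a simulator's methods section: what is modeled,
what is deliberately not, and what passing tests do and do not demonstrate.

## 1. Peptide chemistry (`acquisim.chem`)

Monoisotopic residue masses for the 20 canonical amino acids are taken from
`pyteomics.mass.std_aa_mass`. Fixed constants: proton 1.007276 Da, water
18.010565 Da, methionine-oxidation delta +15.994915 Da. Peptidoforms carry
modifications as `(1-based position, delta)` pairs; eligibility is enforced
per delta (Met-ox only on M). Fragmentation produces b/y series only, ordinals
1..L−1, fragment charges 1..min(2, z−1) (floored at 1) — the charge rule used
for every theoretical spectrum in the package. Precursor enumeration takes
the cartesian product of modification-site subsets (≤ 3 mods) with charges
1–3, ordered deterministically (unmodified first, then by position tuple,
then charge).

A property worth naming: the fractional parts of the 20 residue masses span
0.0919 Da (< 0.1 Da). Any two peptides over this alphabet therefore have
masses whose difference is close to an integer number of daltons, which is
why co-isolated same-charge identifications cluster at 1-Da multiples
(§5).

## 2. Spectrum scoring (`acquisim.scoring`)

The real-time filter and the offline engine share one scoring stack.

**Binning.** Bin width 1.0005079 Da, index = round(m/z / width), intensities
square-root transformed, collisions keep the maximum. Spectra cover
0–2000 Th by default.

**Fast cross-correlation.** Preprocessing = regional normalization (10 equal
bin segments, each scaled to max 50) followed by mean-background subtraction
y′[i] = y[i] − (1/151)·Σ_{τ=−75..+75} y[i+τ] with zero padding. The
theoretical spectrum places 50 at each fragment bin and 25 at the flanking
bins (max-combined); the score is the dot product divided by 10⁴. The
subtraction makes the single dot product algebraically equal to
R(0) − mean(R(τ)) over offsets τ ∈ [−75, 75], which the test suite verifies
against a brute-force offset-correlation oracle to 1e-9 on 500 random
spectra. The vendor real-time implementation is closed; this reconstruction
follows the published SEQUEST/Comet conventions and is a declared
approximation, not a claim about instrument internals. The peak heights
(50/25) and the 10⁴ divisor are calibration constants chosen so that the
operating threshold 0.4 separates self-matches (median xcorr ≈ 1–3 even at
tens of ions) from isobaric non-targets (median ≈ 0, ~10–25% false-pass rate
depending on density).

**Other scores.** dCn = (X1 − X2)/X1 over sorted candidate xcorrs; a single
candidate scores dCn = 1.0 (permissive by design: with a threshold of 0 a
lone confident hit must not be rejected for lack of a runner-up), and
X1 ≤ 0 scores 0. Δppm is signed; filters use the absolute value. Hyperscore =
ln(n_b!·n_y!·max(ΣI_b,1)·max(ΣI_y,1)) with factorial arguments capped at 64.
Spectral contrast angle = 1 − (2/π)·arccos(cosθ) over sqrt intensities at
theoretical fragment positions; with no intensity predictor available the
theoretical vector is uniform, so the angle measures fragment coverage
balance rather than intensity agreement. Fragment matching uses a closed
±20 ppm interval, nearest peak wins, lower m/z preferred on exact ties.

**Filter thresholds.** xcorr ≥ 0.4, dCn ≥ 0, |Δppm| ≤ 5, charges 1–3. The
40 ms real-time search-time cap is carried as metadata only: the simulator
charges no cycle time for real-time search, since on the instrument it runs
concurrently with subsequent ion accumulation and no accounting is available
to emulate.

## 3. Targeting assets (`acquisim.targets`)

Target selection filters a candidate table by length (default 8–11),
replicate presence, and arbitrary per-column rank predicates (e.g. target
allele %-rank < 2, all off-target %-ranks ≥ 10); binder ranks are consumed as
inputs, never computed. Retention-time prediction is a pluggable interface;
the built-in surrogate is a least-squares fit rt = a·(Kyte–Doolittle
hydropathy sum) + b·length + c on ≥ 10 calibration pairs, standing in for an
external deep predictor, and is bypassed entirely when measured RTs are
supplied. Scheduling enumerates all Met-ox/charge variants per target (mod
variants inherit the base peptide's RT — a linear surrogate cannot
distinguish oxidation) and opens closed windows of ±15 min (default) clamped
to the 125-min gradient. The burden profile counts scheduled precursors
whose window contains each time point. Outputs: a one-entry-per-peptide
FASTA for the real-time search space and a minimal vendor-like inclusion CSV
(`Compound,m/z,z,t start (min),t stop (min)`, m/z at 5 decimals); the CSV is
a reconstruction of the idea, not a bit-exact vendor dialect. Precursors
identical in (m/z, z) across different peptides are kept as separate entries.

## 4. Synthetic ground truth (`acquisim.simulate`)

The generator emulates the statistical shape of HLA-I immunopeptidome
samples, not their biochemistry:

| parameter | default | rationale |
| --- | --- | --- |
| length distribution | mode 9 over 8–14, mean ≈ 9.6 | HLA-I length profile |
| abundance | log-normal, σ = 1.5 (ln units) | ~4 orders dynamic range |
| elution | Gaussian, σ = 0.25 min, single apex | simplest shape supporting scheduling logic |
| charge priors | L ≤ 9: (0.2, 0.7, 0.1) over z = 1–3; longer: (0.1, 0.65, 0.25) | short peptides mostly 2+ |
| ionization flux | 2000 ions/ms per abundance unit at apex | sets the detection limit (below) |
| MS1 noise floor | 0.05 ions/ms | features below are invisible |
| MS2 chemical noise | 15 uniform peaks per scan | background matches |
| fragment profile | symmetric Dirichlet, concentration 1.0 | drawn once per peptide and reused, so repeated scans are correlated |

MS1 intensities are expressed directly in flux units, so an MS2 scan over a
window collects min(AGC target, Σ window flux × injection time) ions,
multinomially distributed over the co-isolated peptides' fragment profiles
with Poisson shot noise. This single mechanism produces every acquisition
asymmetry in the package: hMS2 (100 ms injection, AGC 5e5) accumulates ~5×
the ions of sMS2 (20 ms, AGC 1e4) on a flux-limited precursor, and wide
3.2 Th windows co-isolate neighbors into chimeric spectra.

Dilution series multiply spike abundances by the ratio over an identical
background (ratio 0 = negative control). Isobaric interferents are built per
unmodified inclusion entry by bounded rejection sampling over mass-preserving
rearrangements (sequence permutations and I/L swaps) — at ppm-level matching
tolerances only mass-preserving edits can qualify — eluting uniformly inside
the entry's RT window at the entry's charge. They are what the real-time
filter exists to reject.

Determinism: every stochastic step derives its generator from
(master seed, entity token) via CRC-32, so end-to-end runs are bit-identical
and independent of evaluation order. Not modeled: isotope envelopes, ion
mobility, chromatographic drift between replicates (replicate variation
enters only through scan-noise seeds), detector saturation.

## 5. Acquisition engine (`acquisim.acquire`)

Fixed 3-s cycle grid over the gradient; time advances by a full cycle even
when the budget is underused (reproducible, faithful to a fixed cycle time;
variable "top-speed" cycles were rejected for testability). Priority within
a cycle: MS1 (110 ms) → targeted branch → discovery branch; a scan is
acquired only if it fits the remaining budget.

Targeted branch (ilDDA, rtsdda): MS1 features matching an active inclusion
entry (same z, |Δppm| ≤ 10, time inside the window) are queued by intensity
descending (ties by m/z — the ordering is not externally specified).
rtsdda acquires an sMS2 (30 ms), evaluates the real-time filter against all
target peptidoforms in the isolation window, and on a hit acquires an hMS2
(150 ms) if it fits — if not, the event records the hit with no hMS2 and a
flag. ilDDA acquires the hMS2 directly. Targeted scans never read or write
dynamic exclusion and ignore the minimum-intensity gate. ilDDA's inclusion
match requires the same charge as rtsdda's, for comparability.

Discovery branch: TopN (default 10) dMS2 scans (40 ms, 3.2 Th) by intensity,
gated by a minimum intensity (default 40 flux units) and dynamic exclusion
(default 20 s at ±10 ppm after one fragmentation; closed intervals; the
duration is a simulator default, not an externally fixed value).

Per-cycle per-precursor caps are enforced across branches: 3 (rtsdda),
2 (ilDDA), 1 (DDA). A precursor already scanned by the targeted branch stays
eligible for discovery in the same cycle — that is what makes the 3-scan cap
reachable. With an empty inclusion list both targeted methods collapse
exactly onto DDA (verified in tests). Scan durations (110/30/40/150 ms) obey
hMS2 ≤ 5 × sMS2 and are configurable.

## 6. Offline identification (`acquisim.identify`)

Non-enzymatic search of every MS2 scan against a peptide database (all
sample sequences plus the target list in the benchmark) with full-sequence
reversed decoys (palindrome collisions dropped). Candidates must match a
precursor-mass hypothesis within ±10 ppm at the same charge: the isolated
mass always, plus — in chimeric mode — every MS1 feature of the cycle inside
the scan's isolation window that deviates from the isolated mass by more
than 10 ppm (closed-interval assignment; such identifications are labeled
`co_isolated`). One best target and one best decoy are retained per
hypothesis group per scan; no iterative spectrum subtraction is attempted.
Hyperscore ranks PSMs for FDR (xcorr and spectral angle are auxiliary), with
q-values from the conservative (D+1)/T estimator made monotone from the
bottom. Peptide-level filtering (best PSM per stripped sequence, same
estimator) is provided, but run summaries count depth on unique stripped
sequences among accepted PSM-level identifications: with desk-scale
databases of < 100 true peptides, (D+1)/T cannot accept anything at q ≤ 0.01
at the peptide level, which would make depth degenerately zero.

A target identification (TID) is a real-time-search event whose inclusion
peptide is also identified offline on that event's sMS2 and/or hMS2 scan;
discovery-branch identifications of target peptides are counted separately.
The mass-difference analysis takes all same-charge pairs of accepted PSMs
within one scan and reports |Δ neutral mass| residuals against the nearest
integer dalton.

## 7. Benchmark metrics (`acquisim.evaluate`)

Overlap coefficient |A∩B|/min(|A|,|B|) (Szymkiewicz–Simpson, matching the
field's "overlap coefficient"; Jaccard available separately); empty sets are
an error, not a convention. Trade-off ratio = percent target gain per percent
depth loss vs DDA (0 when targets unchanged, ∞ sentinel when there is no
depth loss). The RTS funnel reports events → hits → TIDs with rates and a
zero-denominator flag; TIDs ≤ hits ≤ events is asserted. The reproducibility
matrix cross-tabulates targets by the number of replicates identifying them
under two methods and partitions the target universe. Quantification:
precursor intensity = max MS1 feature intensity over that precursor's PSMs
(charge and ±10 ppm matched within the PSM's cycle; unmatched → 0, flagged),
peptide intensity = sum over its precursors; replicate correlation reports
R² of log10 intensities over shared precursors, split by target status.
"Target sensitivity" is reported both as unique target sequences and as
target PSM counts, labeled distinctly. All rates carry their numerator and
denominator so scaled-down runs stay interpretable.

## 8. Study conditions at desk scale

The package defaults keep the full-scale method parameters (125-min
gradient, ±15-min scheduling windows, 3-s cycles, the filter thresholds and
caps above, dilution ratios 1/16–1/1024 plus negative control). The
benchmark, test suite and acceptance script run scaled-down conditions
chosen once: gradients of 2–8 min with proportionally narrowed ±1–3 min
scheduling windows, 50–250 background peptides, 8–40 targets, 1 isobaric
interferent per unmodified inclusion entry, and 1–3 replicates over ≥ 5
paired seeds for direction checks. Under these conditions the qualitative
pattern of the full-scale method reproduces: the RTS-gated method recovers
several-fold more targets than DDA at 1/1024 at a ~10–25% depth cost, ilDDA
loses the most depth, ~70–90% of real-time events fail the filter, the
negative control yields zero target identifications, and ≥ 80% of
same-charge co-isolation residuals fall within 0.15 Da of an integer.
Magnitudes (hit rates, gain percentages, trade-off ratios) are
scale-dependent and are reported as measured at these sizes; only the
directions are asserted by tests.

## 9. What passing tests do and do not show

The suite demonstrates that the acquisition logic, scoring identities,
filter behavior, FDR arithmetic and metric definitions are correct and
deterministic, and that the claimed mechanisms (ion-statistics advantage of
gated hMS2 scans, chimeric-search gain, 1-Da co-isolation structure,
specificity against isobaric interferents) operate as designed on synthetic
data. It does not validate the signal model against real instrument data:
absolute identification rates, hit rates and trade-off magnitudes on real
immunopeptidomes depend on spectral physics this simulator deliberately
omits.
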