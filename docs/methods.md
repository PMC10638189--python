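# Methods

## Mass model

All arithmetic is monoisotopic and lives in one constants table
(`gagnre.masses.CONSTANTS`). Residue masses are for glycosidically linked
residues (free monosaccharide minus one water): ΔUA 158.021523, UA
176.032088, HexNAc 203.079373, HexN 161.068808 Da. A composition's neutral
mass is the residue sum plus one reducing-end water (18.010565), n·SO₃
(79.956815 each) and, for labeled species, the 2-AB reductive-amination net
addition (2-AB − H₂O + H₂ = 120.068748). Negative-mode ions are
[M + n·DBA − zH]ᶻ⁻ with the proton mass 1.007276 and DBA (C₈H₁₉N)
129.151750 treated as a neutral amine retained on the deprotonated ion.
The gas-phase stoichiometry of the DBA adduct is not established for this
chemistry; the retained-neutral convention is a deliberate choice and is
confined to one term of `ion_mz`, so an alternative convention is a
one-line config change. The unit tests cross-check every ion against an
independent atom-by-atom summation (pyteomics elemental formulas) to
< 1e−4 Th.

Two modeling simplifications follow from what MS1 can distinguish:
N- and O-sulfation are isobaric and pooled into a single SO₃ count, and a
free-amine glucosamine is simply a HexN backbone with neither acetyl nor
N-sulfate — positional and epimeric identity (4S/6S/2S/NS, GlcA/IdoA) is
carried only by `IsomerAnnotation`/`StructureEntry` objects attached to a
composition.

## Composition database and ion catalog

Enumeration is a pure function of an `EnumerationConfig` (class bounds:
terminus, dp, sulfate range, acetylation options, labeled variants). The
default bounds cover internal dp2 (0–3 SO₃, ± acetyl), the unlabeled
internal dp2S2 QC species, NRE dp1 (0–2 SO₃), NRE dp2 (0–3) and the
glucosamine-terminated NRE dp3 (0–4), giving 39 composition records. The
full composition database that this workflow's reference description sizes
at 131 entries spans classes beyond these bounds (its generative rule is
not derivable from the available description); when that table is in hand
it can be transcribed into an `EnumerationConfig` and reproduced exactly.
The corresponding acceptance check is left failing rather than padding the
default config to hit the number.

Catalog expansion caps charge at min(4, sulfates + uronic acids + 1)
ionizable acidic sites, so neutral-sugar dp1 species appear only singly
charged. Sulfate-loss species are generated per parent up to the parent's
sulfate count. Known isobars are intentional and cross-referenced — e.g.
the dp2S2 single-loss ion coincides exactly with the dp2S1 parent at
596.1403.

## Matching and consolidation

A feature matches an ion iff |ppm| ≤ 15 (default) and charges agree
(z = 0 features match any charge and are flagged). All candidates of an
ambiguous feature are kept under one ambiguity group; the preferred
candidate is chosen by smallest |ppm|, then fewer DBA adducts, then fewer
sulfate losses — a deterministic, logged replacement for manual spectral
inspection. Consolidation then uses co-elution evidence: a loss/adduct
candidate is supported only if a parent feature of the same composition
elutes within rt_tol (default 0.2 min, a nano-LC peak width); supported
satellites outrank bare parent candidates for the same feature (this is
what routes the 596.14 trace at the disulfated parent's retention time to
"sulfate loss of dp2S2" while an isolated 596.14 peak stays the dp2S1
parent). Unsupported satellites lose to isobaric lower-sulfation parents
or are flagged `loss_only`/`adduct_only`. Aggregation sums each feature's
intensity exactly once (preferred candidate) per composition, across
charge states, adducts and attached losses; the suite asserts intensity
conservation: assigned + unassigned = input.

Isomer resolution is retention-time based: features of a multi-isomer
composition are assigned to the nearest reference RT within 0.5 min,
respecting the established elution order IdoAGalNAc4S < GlcAGalNAc4S <
GlcAGalNAc6S (32.15/32.66/33.83 min); reference times for structures
without a published anchor are plausible placeholders on the same
gradient. Unresolved intensity stays at composition level with an
`isomer-unresolved` flag instead of being split heuristically.

## MS2 rules

Rules operate on base-peak-normalized intensities; "absent" means < 1% of
base peak. Fragment tolerance is 20 ppm (MS2 is acquired at lower
resolving power than MS1). The GlcA/IdoA call uses the 193.04/175.02
ratio with a dead band (GlcA above 1.5, IdoA below 1/1.5, else unknown).
The 2-O-sulfation call requires 254.98 present and 420.11 absent for
mono-sulfated species; with ≥ 2 sulfates both rings may be sulfated, so
254.98 alone attests the 2S. The 4S/6S call thresholds the 420.11
relative abundance; the *direction* of that difference is not established
quantitatively, so polarity and cutoff are config (default high → 4S,
cutoff 0.40, dead band 0.05) with `calibrate_sulfation_polarity()` to fit
both from standards — before any real-sample use this calibration is
mandatory. GlcNH₂-terminus calls require precursor-mass consistency with a
non-acetylated hexosamine and are upgraded from "tentative" to
"diagnostic" by terminus-retaining fragments (B/C ions of HexN,
configurable list).

## Quantification

All statistics are intensity ratios, hence invariant under global scaling:
per-class relative abundances (sum to 100% by construction), NRE/dp2S1
percentages against the combined ΔUAGalNAc4S + ΔUAGalNAc6S intensity,
GalNAc6S/GalNAc4S from RT-resolved dp1 isomers, and the labeling yield
100·I(labeled dp2S2)/(I(labeled)+I(unlabeled)). Undefined ratios (zero
denominator, e.g. GalNAc6S undetected) propagate as explicit `None`,
never 0 or ∞. Replicate summaries report mean and sample SD; a replicate
missing a key is treated as 0 with a warning. Intensities are summed (not
apexed) across charge states and satellites — the documented default
where the source procedure is silent.

## Biomarker panels

Panels are declarative rule sets. Presence rules fire when a marker
exceeds 1% on the NRE/dp2S1 scale and, where a control reference profile
is supplied, is essentially absent in control (< 0.1%) — except GalNAc4S
(MPS VI), which occurs in controls and therefore requires ≥ 2-fold
elevation over the control reference instead. The MPS IVa rule is
GalNAc6S/GalNAc4S > 0.95, i.e. control mean + 2 SD (0.45 + 2·0.25). The
verdict is the highest-scoring subtype with at least one fired rule, else
"no call". MPS I and MPS II separate through their marker sets themselves
(2-O-sulfated versus plain IdoA structures). Without a control reference
the control-dependent guards are skipped and noted in the call — the
MPS VI rule then loses its specificity, so supplying a reference is the
intended mode. These thresholds are software defaults pending calibration
on larger cohorts; the package makes no diagnostic claims.

## Synthetic data

The generator emulates the observable layer only: per-structure expected
intensities (log-normal noise, CV 15%), charge-state splitting
(0.65/0.30/0.04/0.01 over feasible charges), co-eluting DBA-adduct (10%)
and sulfate-loss (8%) satellites, Gaussian m/z error (σ = 3 ppm, ~5σ
inside the 15 ppm gate), RT jitter (σ = 0.03 min), labeled/unlabeled
splitting of the internal dp2S2 at efficiency 0.91, and uniform-m/z decoys
at 0.2 per true feature. Defaults mirror the study conditions where those
are stated (technical triplicates; NRE fraction 10.3% of total identified
intensity; control GalNAc6S/GalNAc4S 0.45; MPS IVa 1.5; labeling yield
0.91) and typical Orbitrap MS1 behavior where they are not. Phenotype
abundance vectors are qualitative transcriptions of the published
per-subtype patterns (which markers are elevated, reduced, absent), not
digitized bar heights. Each model carries an `expected_call`: treated
MPS I keeps reduced-but-diagnostic markers (its markers demonstrably
persist after transplantation), while treated MPS VI is modeled as almost
normalized and its expected verdict is therefore "no call" — phenotype
recovery is scored against these expected verdicts.

What passing simulation tests do **not** show: performance on real urine
(matrix effects, dilution variance, RT drift between runs, isotope
envelopes, chromatographic peak shapes and co-elution beyond the modeled
satellites are all outside the generator). MS2 fragment templates encode
the qualitative diagnostic rules by construction, so the MS2 round-trip
validates the rule logic and its noise robustness, not the unpublished
4S/6S intensity direction.

## Numerical choices and degenerate inputs

Ties in candidate ranking resolve by a total order ending in the catalog
key, so outputs are order-independent and bit-reproducible for a given
seed/config. Empty inputs return empty results with warnings (empty
feature table, empty MS2 peak list); invalid rows raise with their row
indices; zero denominators yield `None` with a reason logged. Problem
sizes used by the test suite (sub-50 oracle instances, 20-seed cohorts of
8 phenotypes × 3 replicates, 1,000-pair yield simulations) were chosen so
the whole suite runs in seconds on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances.
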