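# Methods

This note documents the statistical procedures implemented in `pvsignal`,
the modelling assumptions behind them, the synthetic data generator used
to validate them, and the numerical and design choices that were
genuinely open.

## 1. Data model and ingestion

FAERS distributes spontaneous reports as quarterly `$`-delimited ASCII
tables (DEMO, DRUG, REAC, OUTC, THER) keyed by PRIMARYID (report version)
and CASEID (safety case). The dialect has no quoting mechanism; on
writing, any `$` inside a value is replaced by `/`.

**Dates.** Only exactly-8-digit strings forming a valid calendar date
parse; partial dates (YYYY, YYYYMM), blanks and impossible days map to
null everywhere. The uniform rule is conservative: a partial date is
treated as unknown in every stage, not just where an interval is
computed.

**Deduplication.** Per CASEID, the version with the highest FDA_DT is
retained, ties broken by the highest PRIMARYID; null FDA_DT sorts lowest.
PRIMARYID comparison needs a total order over arbitrary strings, so
all-digit ids compare numerically and sort before non-digit ids, which
compare lexicographically. The operation is idempotent and never
increases the record count.

**Suspect matching.** A report belongs to the target drug when some DRUG
record has ROLE_COD = PS and a DRUGNAME equal — after trimming,
case-folding and collapsing internal whitespace — to one of the supplied
synonyms (the 12 ELMIRON/PPS name variants ship as a default). Matching
is whole-field: substring matching would capture combination products.
Reports are deliberately not filtered by indication, so off-label use is
retained. Concomitant (C) and interacting (I) roles never qualify.

**Age.** AGE with AGE_COD units YR/DEC/MON/WK/DY/HR is converted to
years; unknown unit codes or out-of-range values (outside 0–130) become
null. Sex is F/M/other → female/male/unknown.

## 2. Disproportionality statistics

For each PT, the case-level 2×2 table uses the full deduplicated database
as comparator: `a` target-drug cases with the PT, `b` without, `c`/`d`
likewise among all other cases. A case counts once per cell regardless of
repeated PT rows.

* ROR = ad/bc, CI = exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)), z = 1.96
  (Rothman-style Wald interval; the criterion literature specifies the
  CI bound but not its construction, and the Wald form is the de facto
  standard in disproportionality work).
* PRR = [a/(a+b)]/[c/(c+d)]; undefined (null) when a margin is empty or
  c = 0.
* χ² is Pearson's statistic with fixed margins, no continuity correction
  by default; a Yates flag exists because the variant is rarely stated in
  published analyses.
* Zero cells: Haldane–Anscombe +0.5 added to **all** cells, applied to
  the ROR/CI only and flagged in the output; PRR and χ² stay on raw
  counts, where they remain well defined whenever their margins are.

**Signal criteria.** A PT is signal-positive when jointly (1) a ≥ 3,
(2) ROR CI lower bound > 1, (3) PRR ≥ 2 and χ² ≥ 4. Whether published
screens require both algorithms or either is often ambiguous; the
per-criterion flags are always reported and the combination rule is
configurable (`and`, the default, or `any`).

Rankings: top-k PTs by report count (or ROR) with alphabetical
tie-breaks; per-SOC summaries keep only signal-positive PTs, ranked by
ROR, with unmapped PTs grouped under `UNMAPPED`. Reporting percentage
uses the number of target-drug cases as denominator.

## 3. Sex-difference screen

Within target-drug reports only, each PT gets a female-vs-male 2×2 table
(unknown sex excluded from this analysis only; those cases remain in the
main screen). ROR and CI as above; the raw p-value is the two-sided
normal tail of z = ln ROR / SE(ln ROR) — a Wald test, since the source
analyses specify no test. p-values are adjusted by Benjamini–Hochberg
across the family of PTs with at least 3 sexed reports (mirroring the
a ≥ 3 floor; smaller families make the FDR family unstable). Direction
is *female* when CI low > 1 and adjusted p < 0.05, *male* when CI high
< 1 and adjusted p < 0.05. Volcano coordinates are (log₂ ROR,
−log₁₀ p_adj) with p floored at 1e-300.

## 4. Outcome seriousness and characteristics

A case may carry several OUTC codes; it is assigned the single most
severe category by the precedence **DE > LT > DS > HO > CA > OT**
(death dominates; published outcome tabulations are mutually exclusive
but rarely state their precedence). RI (required intervention) folds into
"other serious". Cases with no OUTC record are "unknown/non-serious".
The characteristics table stratifies by sex, completed-years age band
(<18, 18–64, ≥65, unknown), reporter type, country, FDA_DT calendar year
of the retained version, and outcome category; percentages use each
family's own total and round to one decimal. Note that published tables
of this kind are not always internally consistent at the rounding digit;
the family-sum convention is applied uniformly here.

## 5. Time to onset

TTO = EVENT_DT − earliest parseable START_DT of the target drug, in whole
days. Exclusions, tallied per reason: missing event date, missing start
date, event before start. Same-day onsets (0 days) are remapped to 0.5
days so log-time likelihoods are defined — only events *before* start are
evidence of a data error; configurable to exclusion instead.

**Kaplan–Meier.** Every included record is an observed event (no
censoring: spontaneous reports contain no follow-up), so S(t) equals
1 − ECDF exactly; the estimator (backed by `lifelines`) is used for its
conventional presentation with a number-at-risk table, n(g) = #{t ≥ g}.

**Parametric fits.** Three families, all with k = 2 parameters:

* Weibull, f(t) = (β/α)(t/α)^{β−1} exp(−(t/α)^β), scale α in days;
* log-normal, ln t ~ N(μ, σ²);
* log-logistic, S(t) = 1/(1 + (t/α)^β).

The log-normal MLE is closed-form. Weibull and log-logistic are
maximized over (ln α, ln β) by Nelder–Mead with moment-based
initialization from the mean and standard deviation of ln t (tolerance
1e-8, iteration cap 500); the log-parameterization keeps the search
unconstrained and well scaled. The shape CI is Wald on ln β with the
observed information from a central-difference Hessian at the optimum.
With the Weibull shape pinned at 1 the scale MLE reduces to the sample
mean (exponential), which serves as an internal closed-form check.

**Model choice and hazard regime.** Families are ranked by AIC
(2k − 2ℓ; BIC = k·ln n − 2ℓ also reported), ties broken by family name.
The Anderson–Darling statistic
A² = −n − (1/n)Σ(2i−1)[ln F(t₍ᵢ₎) + ln(1 − F(t₍ₙ₊₁₋ᵢ₎))] is reported at
the fitted parameters, as a statistic only (no p-value; its null
distribution under estimated parameters is family-specific). The Weibull
shape classifies the hazard: decreasing/early-failure if β < 1 with CI
upper bound < 1; increasing/wear-out if β > 1 with CI lower bound > 1;
otherwise constant/random.

**PT-level comparison.** Kruskal–Wallis (tie-corrected, χ²
approximation, via `scipy`) across PT groups, where a multi-PT case
contributes its onset to each of its PTs — there is no principled
de-overlap rule for multi-reaction reports, so the expansion is
documented and configurable through the per-PT record frame. The
degenerate all-identical case returns H = 0, p = 1. Per-PT mean onsets
flag groups with n < 3.

## 6. The synthetic generator

The generator emulates the structural features of FAERS that the pipeline
must survive, with defaults describing the study conditions the package
targets:

* **Reporting mix**: 87.3% female / 7.1% male / 5.6% unknown (the
  strongly female-skewed profile of a drug indicated for interstitial
  cystitis); reporter codes dominated by lawyers (49%) and consumers
  (30%); ~49% missing age.
* **Events**: each report draws PTs independently (Bernoulli per PT) at
  rate = baseline × drug multiplier × sex multiplier, so the realized
  cross-tabulation converges in expectation to the configured
  disproportionality; at least one reaction per report. Default
  injections: strong ocular multipliers (8–30×) on rare (0.4%) retinal
  terms for the target drug, female-skewed maculopathy terms and
  male-skewed gastrointestinal/bladder terms.
* **Onsets**: Weibull(α = 3097 d, β = 0.62) by default — the scale chosen
  so the median α(ln 2)^{1/β} ≈ 1715 days, a multi-year latency with a
  decreasing hazard; therapy start dates uniform over 2004–2024, FDA
  receipt shortly after the event.
* **Missingness**: 60% missing event dates, 30% missing start dates, 5%
  partial (YYYYMM) dates — so only a minority of cases are TTO-eligible,
  as in real spontaneous data.
* **Duplicates**: 10% of cases emit an older report version sharing the
  CASEID with a distinct PRIMARYID and earlier (or, in ~10% of
  duplicates, tied) FDA_DT and possibly fewer reactions; the ground-truth
  retained version is recorded, making deduplication exactly testable.

What it does **not** emulate: calendar-time reporting dynamics (e.g.
publicity-driven spikes), country structure beyond a constant,
indication fields, dose/duration, or correlation between PTs beyond the
shared multipliers. Passing tests therefore demonstrate correctness of
the algorithms under a known generative model, not the epidemiological
validity of any real-data estimate — in particular, real FAERS RORs for
near-drug-exclusive events can be orders of magnitude larger than
anything a modest synthetic universe produces, and real onset
distributions are mixtures that no single two-parameter family fits.

## 7. Problem sizes and determinism

A single integer seeds one `numpy` generator that drives everything;
fixed seed ⇒ bit-identical tables, manifests and CSVs. Validation suites
run at the sizes where the checked properties are informative: 2×2
statistics against independent oracles on 1,000 random tables; CI
coverage on 2,000 null replicates; Weibull shape recovery on 20
replicates of n = 297 (the TTO cohort size the defaults produce at
~250–300); family selection on n = 5,000 samples; the null FDR screen and
injected-signal detection on 50,000-report universes. The acceptance
script uses a 20,000-report study, which yields roughly 1,000 target
cases and 250 TTO-eligible events.

## 8. Known limitations

* The Wald CI and z-test on ln ROR are first-order approximations; for
  very sparse tables an exact test would be preferable (a Fisher option
  is a natural extension).
* The pairwise PRIMARYID comparison rule cannot be both pairwise-faithful
  and transitive on mixed numeric/alphanumeric ids; the implemented total
  order is faithful on homogeneous ids, the realistic case.
* No censoring is modelled in the TTO analysis; all included records are
  events, which is the spontaneous-reporting convention but understates
  long-latency risk relative to a cohort design.
* Multi-PT expansion double-counts cases across Kruskal–Wallis groups,
  making the groups non-independent; the test is used descriptively.
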