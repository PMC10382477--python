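# Methods

This note documents the statistical procedures, the conventions they
assume, the design choices made where the problem was genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## Data model and screening

A FAERS-style corpus is a set of quarterly `'$'`-delimited bundles:
DEMO (one row per report version), DRUG (one row per drug per report,
with role code PS/SS/C/I), REAC (MedDRA preferred terms), THER
(therapy start/end dates keyed to DRUG rows by sequence number) and
OUTC (outcome codes). A *case* (CASEID) may appear as several report
versions (PRIMARYID) across quarters.

Screening is the standard four-step funnel:

1. **Deduplication.** One report version survives per CASEID: the one
   with the latest FDA receipt date (FDA_DT); ties are broken by the
   highest PRIMARYID. FDA_DT values of reduced precision (year or
   year-month) sort before any more precise date in the same period,
   and wholly missing dates sort before everything — an undated version
   can never displace a dated one. Deduplication is idempotent and
   independent of file-load order. After this step CASEID and
   surviving PRIMARYID are in bijection; all downstream sets use
   PRIMARYID.
2. **Primary-suspect screening.** A case is assigned to target drug
   *d* iff at least one PS-role row canonicalises to *d* and no PS-role
   row canonicalises to a different dictionary drug. Cases with two or
   more distinct dictionary drugs in the PS role are excluded outright,
   making the per-drug case sets pairwise disjoint (so the pooled class
   count is the sum of the per-drug counts). SS/C/I rows never assign
   exposure.
3. **Event extraction.** A case carries the target event iff any REAC
   preferred term equals the target term after trimming,
   case-insensitively. Exact-term matching only: clinically adjacent
   terms (e.g. myoglobinuria against a rhabdomyolysis query) do not
   count.
4. **Intersection** per drug, against the same deduplicated N.

**Drug-name canonicalisation.** FAERS DRUGNAME strings are free text.
A dictionary maps them to canonical generics by searching for any
synonym as a whole-token subsequence of the normalised (upper-cased,
punctuation-stripped) verbatim. Token-boundary matching is load-bearing:
plain substring search would fire the CITALOPRAM synonym inside every
ESCITALOPRAM report and make the two canonicals structurally ambiguous.
A verbatim matching two canonicals raises rather than guessing. There
is no fuzzy/edit-distance matching and no RxNorm/ATC mapping; the
bundled dictionaries carry the six SSRIs and a statin class list,
extensible via `CANONICAL<TAB>SYNONYM` files.

**Co-medication sensitivity.** The statin-exclusion analysis removes
any case carrying a statin row in *any* role — but from the exposure
arm only: the a and b cells shrink while c and d keep their
main-analysis values, and each table's N is the sum of its own cells.
Whether the comparator arm should also lose its statin reports is not
determinable from the reference counts; this reconstruction reproduces
the published statin-excluded class row to within 1% on all eight
statistics (exactly on IC and IC025) and is documented rather than
claimed exact.

## Disproportionality statistics

With cells a, b, c, d, `N = a+b+c+d` and `s = √(1/a+1/b+1/c+1/d)`:

* `ROR = (a·d)/(b·c)`, CI `exp(ln ROR ± 1.96·s)`;
* `PRR = (a/(a+b))/(c/(c+d))`, with the Pearson χ² statistic
  `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, **no** Yates continuity
  correction (the correction would shift the reference value 1037.16
  to ≈1035.3);
* `IC = log₂[a·N/((a+c)(a+b))]`, `IC025 = IC·exp(−1.96·s)`;
* `EBGM = a·N/((a+c)(a+b))`, `EBGM05 = exp(ln EBGM − 1.64·s)`.

Signal criteria: ROR CI lower bound > 1 with N ≥ 2; PRR ≥ 2 with
χ² ≥ 4 and N ≥ 3; IC025 ≥ 0; EBGM05 > 2 — and the overall verdict is
the conjunction of all four. N in the criteria is the case count a.

Three deliberate divergences from the wider literature, inherited from
the reference construction and kept for exact reproducibility:

* **IC and EBGM are the same observed/expected ratio** on log₂ and
  natural scales (`IC ≡ log₂ EBGM`). No empirical-Bayes (MGPS)
  shrinkage and no BCPNN posterior is applied; EBGM here is the raw
  relative reporting ratio, and the IC025/EBGM05 bounds are normal
  approximations using the log-odds-ratio standard error. Canonical
  BCPNN/MGPS intervals would differ, most visibly at small counts.
* **The source tables' formula typos are corrected.** The printed ROR
  form "(a/b)/(c/b)" and the transposed PRR form "(a/(a+c))/(b/(b+d))"
  are algebraically inconsistent with the printed numbers; the forms
  above are the ones that reproduce them, and are the textbook
  definitions in this table orientation.
* **The multiplicative IC025** only lower-bounds IC when IC ≥ 0 (for
  negative IC the factor `e^(−1.96 s)` < 1 moves the value toward 0).
  It is implemented as printed; the ordering `IC025 ≤ IC` is asserted
  and tested only for non-negative IC.

**Zero cells** receive no Haldane–Anscombe 0.5 correction: a = 0 gives
ROR 0 with an undefined CI, a zero comparator cell gives an infinite
ratio, affected statistics are flagged in `SignalResult.undefined`,
and the corresponding criteria simply fail. The N-based criteria
already exclude the tiny-count region where the correction matters.

**Monotonicity caveat.** ROR and PRR are strictly increasing in a with
b, c, d fixed. IC/EBGM are strictly increasing only while the
comparator margins dominate (`1/a + 1/N > 1/(a+b) + 1/(a+c)`); with
tiny margins the observed/expected ratio can turn over because N grows
with a. The property tests assert monotonicity in the dominant-margin
regime, which is the spontaneous-report setting.

**Display rounding** is decimal half-up to 2 places (matching the
printed-table convention; banker's rounding would differ on exact
half-cents). Full precision is retained everywhere internally.

## Descriptive analyses

* **Age** is normalised to years from AGE/AGE_COD (YR ×1, DEC ×10,
  MON ÷12, WK ÷52.18, DY ÷365.25, HR ÷8766); unknown unit codes or
  values outside [0, 130] are treated as unknown. Bands are <18,
  18–65 and >65 with **65 inclusive in the middle band** (the boundary
  assignment is a convention; the band labels do not determine it).
* **Time-to-onset** is EVENT_DT − START_DT in days, where START_DT
  comes from the THER row linked (via `dsg_drug_seq`) to a PS-role row
  of the case's assigned drug; with several linked rows the earliest
  full-precision start date is used. Only full calendar dates enter the
  arithmetic — partial dates are "inaccurate" and excluded, as are
  negative durations and cases with no linkable therapy row. Exclusion
  reasons partition the non-evaluable cases in a fixed priority order
  (no therapy row → unusable start → unusable event → negative).
  Quartiles use linear interpolation between order statistics
  (`numpy.percentile` default). Same-day onset (0 days) is evaluable.
* **Outcomes** count distinct cases per code in {DE, LT, HO, DS, RI,
  OT}; the legacy CA (congenital anomaly) code is folded into OT with
  a log note. Codes are not mutually exclusive, so proportions can sum
  above 1.
* **Reporter class** maps occupation codes {MD, PH, OT, RN, HP} to
  health-professional and {CN, LW} to consumer/lawyer; anything else is
  unknown. **Country** prefers the occurrence country and falls back to
  the reporter country.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis relies
on, with exact bookkeeping. Per case: one PS drug (six SSRIs at
FAERS-plausible marginal exposure probabilities summing to ~9%, the
rest a background pool); each event term with probability
`min(1, p_e·λ(d,e))` where λ is the injected drug–event
reporting-rate ratio (1 under the null; rhabdomyolysis baseline
p = 0.01); a filler term when no event fires, so REAC is never empty;
therapy start before the FDA date with event = start + round(log-normal
onset) (μ = ln-scale 3.0, σ = 1.8 — median ≈ 20 days with the heavy
right tail typical of onset histograms); missing/partial-date, missing
demographic, date-error (event before start), statin co-medication
(5%), duplicate re-emission (20% later-FDA_DT plus 2% same-FDA_DT to
exercise the PRIMARYID tie-break) and multi-suspect (1%) injections.
PRIMARYID is CASEID×100 + version. Generation is vectorised and a pure
function of the config: one seed, byte-identical files.

What it does **not** emulate: drug-name misspellings and coding drift,
realistic country/indication distributions, cross-CASEID duplicates
(two CASEIDs for one clinical event — undetectable by the CASEID rule
by construction), report-version content changes, and ISR-era file
layouts. Passing the recovery tests therefore demonstrates the
correctness of the screening *logic* under the stated conventions, not
robustness to real-world name noise.

## Validation problem sizes

The suite validates at desk scale: screening recovery on five corpora
of 50,000 cases (one routed through the on-disk dialect and back);
estimator consistency with λ ∈ {1, 2, 5} over 20 seeds × 200,000 cases
(median pipeline ROR within 10% of λ; the null condition signal-free in
≥ 95% of seeds — note the ROR estimates a reporting-odds ratio, so a
small upward bias relative to the injected rate ratio appears as the
event stops being rare); and the exact reproduction of the published
pooled-class row from its four screening margins, which is independent
of corpus size. The full 16-million-report archive is supported by the
same code paths but is deliberately outside the test envelope.

## Known limitations

* Margins-only entry points can reproduce published class-level rows
  exactly; published per-drug rows are not recomputable without the
  per-drug exposure totals, which the reference counts do not include.
* The statin sensitivity reconstruction is one of several defensible
  comparator treatments (see above); it is validated to 1%, not to
  printed precision.
* No stratification, masking adjustment, or shrinkage: estimates at
  very small a are noisy and the N-criteria are the only guard.
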