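# Methods

## Day-roost assignment and QC

Detection streams are antenna reads `(tag_id, roost_id, timestamp)` in one
configured local time zone (naive datetimes; the zone's rules are the only
daylight-saving handling). The day roost for `(bat, date)` is the roost of
the last detection *strictly before* that date's sunset; a read at exactly
sunset is excluded so the boundary is deterministic. Dates with no
pre-sunset read get no assignment (an optional fallback assigns the last
pre-sunrise read with `basis="pre_sunrise_only"`; off by default).
Assignment is idempotent and independent of input row order.

Sun times come from a provider interface with two implementations: a
per-date table, and a NOAA solar-position approximation (fractional-year
expansion, refraction-corrected zenith 90.833°) parameterized by latitude,
longitude and a fixed UTC offset. Defaults are 47.3 N, 53.3 W, UTC−2:30 —
the monitored colony's location and summer clock. The approximation is
accurate to a couple of minutes, far finer than the spacing of roost reads
around the sunset boundary.

The sunrise QC statistic is the fraction of assigned records whose
pre-sunset roost matches the last read before the *same* morning's sunrise.
Records without a pre-sunrise read are excluded from the denominator: the
statistic measures disagreement where a comparison exists, not detection
completeness. With no comparable records it is reported as NaN.

Inclusion filters keep females who are adults in the window's year (bats
captured as juveniles qualify from the year after capture; exact age =
year − cohort year) with at least `min_obs = 10` assigned days inside
[28 April, parturition cutoff]. Parturition cutoffs are per-year config —
they come from an external assessment, not from the data. Unknown-age
adults are retained in networks; age-specific outputs are simply not
emitted for them.

## Association networks

The Simple Ratio Index is computed from a day-by-individual occupancy
array. Dyads with zero joint sampling (neither bat observed on any day) are
set to SRI 0 and flagged rather than NA, so downstream matrix regressions
always see complete matrices; the flags support sensitivity re-runs. The
conservation identity `x + y_AB + y_A + y_B = #days at least one observed`
is asserted by property tests, and the whole computation is certified
against a brute-force recount on 1000 random small instances.

Cross-year comparisons align networks on the intersection of bats
qualifying in both years, computed at comparison time (each year's network
is built on all of that year's qualifying bats). Comparisons with fewer
than `min_shared_bats = 4` common bats are skipped.

## Lagged association rate

The estimator is the ordered-pair rate
`g(τ) = Σ_t #{(i,j): together at t and t+τ} / Σ_t #{(i,j): together at t, i
observed at t+τ}`, evaluated over all day pairs of the full multiyear
record; fall–winter gaps appear simply as large lags. Default binning is
daily to 90 days then log-spaced, because multiyear lags are sparse. A
variant conditioning on each dyad's *first* association day (so the curve
reads "persists τ days after it first occurs") is available behind a flag;
the all-pairs estimator is the default and the two are not claimed to be
interchangeable. No jackknife or standard errors are attached.

The null level is the mean over individuals of (# distinct ever-associates)
/ (N − 1) — the rate expected if bats re-drew partners at random from their
associate pool. With incomplete detection both the LAR and the null are
attenuated by the detection probability of the partner; comparisons between
them are qualitative.

## Roost-fidelity control

Per-bat roost-use profiles are proportions over *assigned* days only —
undetected days are treated as missing at random. Roosts unmonitored in a
year are dropped from that year's index before normalization. The
co-occurrence matrix `P_ij = Σ_k p_ik p_jk` is exactly the expected dyadic
co-roosting rate when bats choose independently from their profiles; in the
simulator with no social attraction and full detection, empirical
co-roosting frequencies converge to `P` (asserted within Monte-Carlo error
over 5000 days), which is what licenses `P` as the no-social null in the
matrix regression.

## Matrix inference

Dyadic observations share nodes, so all significance comes from node
permutations (joint row+column relabelling). P-values use the +1
convention, `(#extreme + 1)/(n_perm + 1)`, with 999 permutations by default
(odd, so attainable levels include 0.05 exactly); two-tailed is primary and
one-tailed is also reported. All permutation draws flow from explicit
generators; the pipeline derives a named substream per stage from one root
seed, so re-running one stage never perturbs another.

**Mantel.** Pearson correlation (Spearman behind a flag) of upper-triangle
entries, null by permuting one matrix's nodes. Constant matrices yield NaN.
Calibration — rejection at the nominal 5% under independence — is asserted
over 500 replicates.

**MRQAP-DSP.** The dependent and all predictor matrices are standardized by
z-scoring their off-diagonal entries (`scale_matrix`), so OLS coefficients
on the vectorized upper triangles are scaled effect sizes comparable across
predictors; this standardization is this package's convention, chosen
because effect magnitudes are compared across predictors of different
units. Significance per predictor follows Dekker's double semi-partialling:
the predictor's matrix is residualized on the remaining predictors, the
residual matrix is node-permuted, the model refit, and |coefficient|
compared. DSP keeps the test calibrated when predictors are mutually
correlated — the exact situation of previous-year SRI vs co-occurrence —
and this is asserted by a calibration run (null predictor correlated 0.6
with the true one) plus a planted-coefficient recovery at N = 50. In the
recovery construction the noise variance is set so the dependent matrix has
unit variance; the planted values are then themselves the scaled effects.
Collinear predictor sets (design condition number > 1e8) are rejected with
a diagnostic.

**Fold difference.** Co-occurrence effect ÷ previous-year effect. A zero
divisor yields an explicit undefined (None), never infinity.

## Individual metrics and the cohort comparison

Metrics are computed on the full yearly networks (known- and unknown-age
bats) and reported for known-aged bats only: degree (# associates with
SRI > 0), unnormalized betweenness on the binary SRI > 0 graph (weighted
variant with edge length 1/SRI behind a flag; binary is the default as the
conservative reading of a connection-count metric), and CV SRI = sample
sd/mean of a bat's dyadic SRIs, zeros included by default (a flag excludes
them). Degree and betweenness are certified against exhaustive
path-enumeration oracles on 500 random graphs. Age regressions are simple
OLS pooled over bat-years; per-age sample counts are reported. Per-bat
trajectories across ages are deliberately not modeled.

The cohort comparison computes, per known-aged bat and year, its mean SRI
to same-cohort and to different-cohort known-aged bats (cohort membership
is unknowable for unknown-age associates, so both means are restricted to
known-aged bats), averages each bat across years, and runs a paired t-test
across bats; the analysis starts in the first year whose network has at
least two known-aged bats.

**Known limitation.** The paired test treats bats as independent, but each
dyad appears in both of its members' means. Under pure dyadic
exchangeability this doubles the variance of the mean paired difference
relative to the t-test's estimate (inflating the type-I rate to roughly
16%, for any cohort and colony size), so the test's realized size under a
cohort-blind world is above nominal. The test is implemented exactly as
specified and its anticonservativeness is documented rather than patched;
detection of a genuinely planted cohort effect is what the recovery run
certifies.

## Synthetic colony

The generator is a leader–follower sequential-placement model, chosen over
joint samplers because it is O(N·K) per day and plants a social signal
orthogonal to the preference structure — the precise confound the matrix
regression must resolve. Each day bats are placed in random order; a bat
follows an already-placed partner (option weight `w_social ×` summed
affinity to placed partners, partner drawn proportional to affinity) or
samples from its own availability-renormalized Dirichlet roost-preference
vector (weight `w_fidelity`). With `w_social = 0` the expected dyadic
co-roosting rate is analytically `Σ_k p_ik p_jk`.

Affinity has sparse "preferred associate" structure: a dyad carries
positive (exponential) affinity with probability `affinity_partners/(N−1)`,
with strengths scaled so a bat's total affinity is O(1) — the
follow-vs-prefer odds are then stable in colony size and the social signal
concentrates on specific dyads, as preferred associations do in real
colonies. Year-to-year, affinity mixes as `ρ·A + (1−ρ)·fresh`; bats are
lost with probability `p_annual_loss` and juvenile recruits (cohort year =
entry year, network-eligible from the following season) are added with
fresh preferences and affinities. Cohort assortativity multiplies the
*bond-formation rate* within known cohorts, so expected within-cohort
affinity scales by exactly the assortativity factor while individual bond
strengths stay realistic.

Default study conditions (fixed once): 60 adult females, 10 roost boxes,
80-day seasons from 28 April, detection probability 0.7 per bat-day,
pre-sunrise read probability 0.9, morning/evening roost-switch probability
0.031 (reproducing ~96.9% sunrise agreement), `w_fidelity = 1.0`,
`w_social = 0.5` (fidelity-dominant with a real social signal, the regime
the matrix regression is designed for), preference concentration 0.5
(roost specialists), full affinity persistence, 20% annual loss with 12
recruits/year, 30% of founders with known birth cohorts (tagged as
juveniles one to five years pre-study). An availability schedule can open
fewer roosts early in the season (off by default).

**What the simulator does not emulate:** sporadic within-season attendance
(every present bat roosts daily; missingness is purely observational),
within-roost spatial assortment, thermoregulatory roost choice, relatedness
structure, and bat-level heterogeneity in gregariousness. Passing tests
therefore certify the estimators and their calibration under the stated
generative assumptions, not the field realism of any particular parameter.

## Problem sizes and numerical choices

Acceptance runs use the sizes their checks need rather than field scale:
oracle equivalence on ≤ 6-bat/≤ 20-day instances (1000 of them, exact),
calibration at N = 20 matrices with 999 permutations (500 Mantel / 300
MRQAP replicates), end-to-end recovery on 50 four-year colonies of 60
bats, Mantel-decay trends on 30 five-year colonies of 40 bats, and cohort
recovery on 50 four-year colonies of 40 bats. The Mantel-decay
full-persistence arm runs without turnover, because recruitment itself
dilutes surviving bats' affinity budgets and produces a small genuine
decay unrelated to affinity persistence. SRI ties and zero denominators
resolve as described above; permutation p-values never report 0; matrix
standardization uses the sample (n−1) standard deviation throughout.
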