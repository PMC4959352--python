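# Methods notes

## Model and assumptions

The package models each species' abundance as an independent birth–death
chain with per-capita birth rate `b` (1/time), per-capita death rate `d`
(1/time) and a constant influx `S` (individuals/time) absorbed into the
birth term, `b_n = b(n + S/b)`, `d_n = d·n`. Neutrality means all species
share (b, d, S); stationarity requires `b/d < 1`. Under these assumptions
the stationary abundance law is a Negative Binomial in `x = b/d` and
`r = S/b`, and the community RSA is its zero-truncated form scaled to the
observed species count. Everything downstream — the Preston-binned fit, the
total species count `N = N_obs/(1 − (1−x)^r)`, and the biodiversity number
θ — follows from those two ratios. Species interactions enter only through
the mean-field influx term; the fit's systematic residuals in the abundant
tail of real communities are exactly where that assumption is expected to
break first.

## Parameters that matter

- `ratio_bd = b/d` ∈ (0,1): controls the tail; values near 1 give long,
  log-normal-looking tails. No default — it is fitted.
- `ratio_Sb = S/b` > 0: the shape parameter; → 0 recovers Fisher's
  log-series, larger values produce an interior mode. Fitted.
- Clustering thresholds: default sweep {0.90, 0.93, 0.95, 0.97}, the
  conventional spread of phylogenetic scales for 16S OTUs.
- `filter_level` (default 1): removes the rarest OTUs as likely sequencing
  artefacts. Level 1 decrements every abundance by one and drops emptied
  species, i.e. "remove one read per OTU" — singletons vanish, doubletons
  become singletons. A `drop` mode discards rare species without
  decrementing the survivors, since conventions differ between studies.
- Alignment scoring (pinned for reproducibility): match +1, mismatch −1,
  gap open −2, gap extend −1, end-to-end (Needleman–Wunsch); a length-g gap
  costs 2 + (g−1). Identity is the fraction of alignment columns with
  identical letters; every gap column, terminal ones included, counts
  against identity.

## Synthetic data

The generator produces the three input classes the pipeline consumes.

*Abundances* are drawn from the zero-truncated stationary law by
inverse-CDF sampling on a tabulated pmf (log-gamma evaluated, truncated
where the remaining tail mass is below 1e-12) — tabulation avoids the bias
rejection samplers develop as `b/d → 1`. *Dynamics* come from an exact
Gillespie simulation of the two reactions, JIT-compiled, with the state
recorded at fixed time intervals after a burn-in; interval sampling rather
than per-event sampling avoids event-frequency bias in occupancy estimates.

*Read communities* plant a two-level hierarchy: one ancestor per OTU is
mutated from a shared random root with a Poisson(L·D/2) substitution count,
so two ancestors sit near pairwise divergence D (no-back-mutation
approximation; collisions make realised divergence slightly smaller), and
each read mutates from its ancestor at an independent per-base substitution
rate. Substitutions are uniform over the three alternative bases; indels,
chimeras, quality scores and platform-specific error profiles are *not*
emulated, and divergence is single-level (no deep taxonomic hierarchy), so
clustering results on synthetic data demonstrate correctness of the greedy
procedure, not robustness to real amplicon noise. Within-OTU pairwise
identity is approximately `1 − 2·read_divergence` with Binomial(L)
fluctuations: configurations should keep `2·read_divergence` several
standard deviations clear of `1 − threshold` if exact recovery is expected.

## Numerical choices

- All Γ and power terms go through `gammaln`/`log1p`/`expm1`; θ is evaluated
  fully in log space so Γ(r) at r ~ 1e-8 and powers at x → 1 survive.
- The detailed-balance product is accumulated in log space and normalised by
  the finite sum; a geometric bound on the truncated tail must be < 1e-12 or
  the call raises rather than returning a silently biased table.
- Expected octave counts are survival-function differences of the Negative
  Binomial (`sf(2^k − 1) − sf(2^{k+1} − 1)`), which keeps relative accuracy
  deep in the tail where cdf differences cancel.
- The fit searches (logit x, log r) — the domain enforced by the transform,
  no constrained solver — with Nelder–Mead from a fixed 4×2 grid of starts
  (x ∈ {0.5, 0.9, 0.99, 0.999} × r ∈ {0.05, 1}), `fatol` 1e-10, at most
  10^4 evaluations per start; the best incumbent is returned with a
  `converged` flag. `n_obs` stays fixed at the histogram total during the
  search; N and θ are derived afterwards. Model mass beyond the observed
  octaves is not folded into the last bin; it is reported as `tail_mass`.
- R² is computed on raw octave counts about their mean. Least squares on
  octave counts is the default and documented fit; a multinomial
  maximum-likelihood mode is available behind `mode="mle"` for comparison.
- Histograms with fewer than three non-empty octaves raise
  (two parameters cannot be constrained by two points); an octave pattern
  inconsistent with the family (e.g. a rising tail) still returns the
  least-squares optimum with its R², never a silent failure.

## Clustering design choices

The greedy pass takes the first record as the first seed and assigns each
later record to the **first** seed (in creation order) meeting the
threshold, founding a new cluster otherwise; `assign="best"` switches to
highest-identity assignment with earliest-seed tie-break. Input order
matters, and quality scores are unavailable for synthetic reads, so the
default rank is descending length, then descending exact-duplicate count,
then id — deterministic; `keep_input_order` bypasses it. Sequences are
compared as-is (no reverse-complement search). Among co-optimal alignments
the aligner's first reported one defines the identity fraction; co-optimal
paths can differ in a gap-column placement, so identity values at exact
score ties are pinned only per aligner version.

## Diversity

Hill numbers use the same post-filtering abundance vector the fit sees, so
θ, H₁ and H₂ describe the same community; `diversity_prefilter=True`
switches to pre-filter frequencies.

## Validation scales

The shipped checks run the oracle comparison to n = 200 over a 3×3 (x, r)
grid, Gillespie at 10^5 interval samples for three rate sets, parameter
recovery over 50 communities of 1000 species, and planted-cluster recovery
on a 50-OTU / 2000-read community (300 bp, within-OTU read divergence
0.003, between-OTU ancestor divergence 0.25) plus 100 randomized small
instances replayed against a quadratic oracle.

## Known limitations

- The greedy procedure guarantees member-to-seed identity ≥ threshold, not
  a maximum within-cluster diameter.
- No alignment heuristics: clustering is exact but quadratic in practice
  (every read against every earlier seed), so it targets communities of
  thousands, not millions, of reads.
- The singleton-decrement convention shifts the whole RSA left before
  fitting; fitted S/b therefore depends on the filtering convention, which
  is why both conventions are exposed.
- Occupancy estimates use correlated interval samples; intervals of a few
  relaxation times 1/(d − b) are needed for the effective sample size to
  approach the nominal one.
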