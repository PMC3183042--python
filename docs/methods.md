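# Methods

## The secondary-contact model

Two incipient species of constant diploid size $N$ separate, then meet
again long before the present: gene flow occurs at symmetric per-capita
rate $m$ per generation during a window of length $T$ (units of $2N$
generations) and stops early enough that each species is reciprocally
monophyletic at every locus today. A locus whose between-species
coalescence falls inside or after the window (backward in time: the two
lineages were brought together by migration) appears *short* —
introgressed; a locus coalescing before the original split appears *long*.
Gene trees are assumed to be inferred without error, and discordance from
incomplete lineage sorting is excluded by the model's premise of ancient
splits; the question is purely whether migration was sex-biased.

Female and male per-capita rates are $m_F = 2mp$ and $m_M = 2m(1-p)$ with
$p$ the female fraction of migrants; $2Nm$ is then the expected number of
migrant autosomal copies per generation, and $N(m_F+m_M) = 2Nm$ migrant
autosomes, $\tfrac12 N m_F$ mitochondrial and $\tfrac12 N m_M$ Y copies
move per generation. Male and female effective sizes are assumed equal.

## The two-lineage chain

One lineage per species enters the window in state "different
populations". Per generation, each lineage migrates independently with the
marker's per-copy probability $m_\ell$, and a cohabiting pair coalesces
with probability $c_\ell = 1/(2N_{e,\ell})$. Probabilities of two
simultaneous events are dropped, giving the first-order transition matrix
in the README. The window's $2NT$ generations are applied as a matrix
power (exponentiation by squaring; a stepwise debug path is retained —
differences are below $10^{-12}$). Accumulated float round-off in the
probability sum is renormalized, but only within $10^{-9}$; anything
larger raises.

Marker parameterization:

| marker | $m_\ell$ | copies | $c_\ell$ |
|---|---|---|---|
| autosome | $(m_F+m_M)/2$ | $2N$ | $1/(2N)$ |
| X | $(2m_F+m_M)/3$ | $3N/2$ | $2/(3N)$ |
| Y | $m_M$ | $N/2$ | $2/N$ (default) or $1/N$ |
| mitochondrial | $m_F$ | $N/2$ | $2/N$ (default) or $1/N$ |

**Mito/Y coalescence convention.** The uniparental systems have $N/2$
transmitting copies, so the pairwise coalescence probability is $2/N$
(`copy_count`, the default). Describing them as "effective size $N/2$" and
applying the diploid formula $1/(2N_e)$ instead gives $1/N$
(`paper_literal`). The two readings differ by a factor of two for mito/Y
only (they coincide for X), and the difference matters: the reference
decision thresholds this package reproduces (the five-autosome minimum,
the reference decision suite) hold under `copy_count` and not under
`paper_literal`, so `copy_count` is the default; both remain selectable
and the acceptance script prints the thresholds under all four convention
combinations.

**Short-branch rule.** At the (backward) end of the window a pair is
coalesced, cohabiting, or separated. Cohabiting pairs trace through at
least one migrant and, because the species stay isolated long after the
window, must coalesce within the donor species — an introgressed
genealogy. The default `coalesced_or_same_pop` therefore classifies them
as short; `coalesced_only` is the conservative alternative and is what the
strong-migration closed form $1-e^{-cT/2}$ checks.

## Continuous-time oracle and Monte Carlo oracle

Two independent checks guard the chain. (1) Its continuum limit: with
scaled rates $M = 2N m_\ell$, $c = 2N c_\ell$ per unit of $2N$
generations, the rate matrix has transient block
$\bigl(\begin{smallmatrix}-2M & 2M\\ 2M & -2M-c\end{smallmatrix}\bigr)$;
the matrix exponential gives the exact law, independent of $N$. The
discrete chain converges to it at $O(1/N)$: the maximum state-probability
gap is below $10^{-3}$ at $N = 1000$ and $10^{-4}$ at $N = 10000$ across
the test grid. The CTMC law depends only on $(MT, cT)$ — the true
rescaling invariance. (2) A Monte Carlo simulator that replays the
generative model *without* the first-order approximation: each generation
both lineages draw Bernoulli migrations (the pair toggles cohabitation
when exactly one moves, probability $2m_\ell(1-m_\ell)$), then a
cohabiting pair draws coalescence. The default engine jumps between events
with exact geometric waiting times (a pair rejoined at generation $t$
already faces that generation's coalescence draw, since migration precedes
coalescence within a generation); a literal per-generation engine
cross-validates it at small $N$. Simulator and chain agree within three
binomial standard errors at $10^6$ replicates across
$2Nm \in \{0.1, 1, 5\} \times$ {autosome, mito, Y}; the residual
second-order bias at the most extreme cell is $\sim 1.5\times10^{-4}$,
well inside that tolerance.

## Inference

The pattern log-likelihood $\sum_r n_r \log \pi_r$ is evaluated on a grid
of 201 log-spaced $2Nm$ values on $[0.01, 10]$ × 201 equally spaced $p$
values on $[0, 1]$ (containing $p = 1/2$ exactly so the null is a grid
line). Per-marker short-branch probabilities over the whole grid are
computed by a batched matrix power and cached, so scanning many patterns
on one grid costs one chain evaluation per marker. Impossible records
contribute $-\infty$, which participates in max/compare semantics; a
pattern impossible everywhere raises a named error. The MLE is the set of
grid argmaxima (ties reported, never broken or interpolated); the 95%
region is $\{2(\hat\ell-\ell) \le \chi^2_{1,0.95}\}$ with the exact
quantile, per the framework's stated 1-df convention. Rejection of
$p = 1/2$ by the profile LR is asserted equivalent to the region excluding
the equal-rate line. The min-loci scan exploits log-linearity in counts:
base and increment surfaces are computed once and each candidate count is
a weighted re-reduction. A warning (and a JSON flag) is raised when the
region touches the $2Nm$ boundary, since the scan range truncates it; the
upper bound 10 matters — widening it to 100 moves the five-autosome
threshold to four, so the bounded default is part of the reproduced
conditions.

## Synthetic data

`simulate_pattern` draws each locus's branch independently (unlinked
loci), one substream per marker class spawned from the root seed so
results are independent of iteration order and byte-identical under a
fixed seed. It emulates exactly the inference model — no mutation, no
tree-estimation error, no incomplete lineage sorting, equal sex-specific
effective sizes, symmetric migration, a single panmictic population pair.
Passing recovery tests therefore show the estimator is consistent with its
own generative assumptions, not that real data meet them.

## Numerical and design choices

- $N = 1000$ by default: discretization error $O(1/N)$ is below $10^{-3}$,
  under anything that moves a decision; configurable.
- Grid scans report all argmax ties; $p \in \{0,1\}$ is admitted and the
  resulting zero probabilities become $-\infty$ log-likelihoods rather
  than errors.
- All file output uses 12 significant digits; patterns are JSON or TSV,
  surfaces TSV, results JSON with the resolved run configuration embedded.
- $T = 1$ throughout the reference analyses. Results are *not* invariant
  under rescaling $(2Nm, T) \to (2Nm/2, 2T)$: the coalescence clock also
  runs for $T$, so the law depends on $(2Nm\cdot T, T)$ jointly. The exact
  invariance is the CTMC rescaling $(M, c, T) \to (M/2, c/2, 2T)$.
  Decisions are stable between $T = 1$ and $T = 2$; at $T = 0.5$ the
  five-autosome pattern no longer rejects.

## Limitations

- The 95% region uses the $\chi^2_1$ threshold while scanning two
  parameters. Its *joint* coverage of the true $(2Nm, p)$ is therefore
  $P(\chi^2_2 \le 3.84) \approx 85\%$ (measured 86% over 200 simulated
  50-loci-per-marker datasets), while each single-parameter profile
  interval covers at the nominal ~95% (measured 97% for $p$, 94.5% for
  $2Nm$). The 1-df convention is retained because the equal-rate *test* —
  the package's decision — profiles a single constraint and is correctly
  sized.
- Asymmetric population sizes, asymmetric migration, more than two
  populations, selection on migrants, and estimation of $T$ or of
  individual migration times are out of scope.
- Z/W systems are not named explicitly; swap the sexes (mirror symmetry
  $p \to 1-p$ exchanges the uniparental markers exactly) to apply the
  machinery.
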