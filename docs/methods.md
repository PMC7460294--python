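# Methods

## Model

A microarray experimental situation (MES) is a gene set $N$ with two
expression matrices over it: reference samples $S_R$ (normal tissue)
and disease samples $S_D$. The package builds two cooperative-game
rankings from an MES.

**Out-of-range discriminant.** Disease entry $(i, j)$ is declared
normal (set to 0) when it lies inside the closed interval spanned by
gene $i$'s values across *all* reference samples, and retained verbatim
otherwise. This is a deliberately crude per-gene range test: it assumes
the matrices are already pre-processed (normalised, log-transformed as
appropriate) and that the reference samples span the normal dynamic
range of each gene. With few reference samples the observed range
under-covers the true one and the discriminant over-calls abnormality;
no correction is attempted. Missing values are a hard error — there is
no imputation, and no probe-to-gene mapping (identifiers are opaque
strings).

**Co-expression network.** Gene similarity is the absolute Pearson
correlation of discriminant rows (configurable to raw disease rows).
Correlation of a constant row is undefined; such rows get similarity 0
to every partner, with a warning. The unweighted network keeps link
$ij$ iff $s_{ij} \ge \tau$. The tie at $s = \tau$ resolves to "link
present", matching the convention that the threshold is the lowest
admitted similarity. Similarities are computed and compared at full
float precision; any rounding is display-only. A soft-threshold power
transform $s^\beta$ is provided for diagnostics but the games are
defined on unweighted networks only; automatic scale-free-topology
selection of $\tau$ or $\beta$ is out of scope.

**Microarray network game.** With supports $g^E_i$ (links incident to
gene $i$), the value function is
$v(g) = |\{i : \emptyset \neq g^E_i \subseteq g\}| / n(g^E)$, where
$n(g^E)$ counts genes with at least one link. $v$ is the mixture
$\frac{1}{n(g^E)} \sum_i u_{g^E_i}$ of unanimity basis games on the
supports; the $\bar\alpha$ coefficients count genes per distinct
support and always sum to $n(g^E)$. $v$ is monotone under link
addition and $v(g^E) = 1$.

**Link Relevance Index.** The LRI is the position value of this game:
the Shapley value of the game played by the *links*, split equally
between each link's endpoints. It is the unique allocation rule
satisfying efficiency, additivity, superfluous-link invariance, and
link anonymity on this class. The unanimity decomposition collapses it
to a support sum — for a query network $g$,
$F_i(g) = \frac{1}{2 n(g^E)} \sum_{j:\, \emptyset \ne g^E_j \subseteq g}
|g^E_j \cap g_i| / |g^E_j|$ — and on the full network to the degree
form $F_i = \frac{1}{2 n(g^E)} (1 + \sum_{j \sim i} 1/\deg(j))$.
Isolated genes score 0: they contribute no basis game, and only with
this convention does the allocation sum to $v(g^E) = 1$. The
exponential subnetwork-enumeration formula is implemented solely as a
verification oracle, guarded to 12 links.

**Shapley baseline.** The Boolean matrix (1 where the discriminant kept
a value) defines the classical microarray game: $v(T)$ is the fraction
of arrays whose support is a non-empty subset of $T$. All-normal arrays
never win but stay in the denominator. The game is the mixture of
unanimity games on the supports, giving the closed form
$\Phi_i = \frac{1}{|S_D|} \sum_{j: i \in sp(j)} 1/|sp(j)|$, verified
against the factorial brute force in the property suite.

## Numerical choices

- Every game-theoretic quantity is a ratio of small integers, so scores
  are computed with `fractions.Fraction` and the worked-example and
  oracle tests assert *exact* equality. Score files are written as
  floats; the pipeline re-checks efficiency of the emitted float table
  to 1e-9.
- Ranking ties are always broken lexicographically by gene id. This is
  load-bearing: top-k overlap counts near ties are otherwise
  non-deterministic.
- Links are stored canonically (smaller id first, lexicographic) and
  all set iterations are ordered, so byte-identical inputs give
  byte-identical outputs; each pipeline run writes a manifest (config
  echo + version) sufficient to reproduce it.
- Degenerate inputs: an empty network after thresholding is a warning,
  not an error — the network game needs at least one link, so scoring
  is skipped and an empty score file written. Fewer than two disease
  samples is an error (no correlation exists).

## Synthetic data generator

`genegames.synthetic.generate_mes` emulates a case/control experiment
with planted co-expressed modules. Per-gene baselines are uniform on
[2, 10] with Gaussian reference noise (s.d. 0.5, 20 reference and 30
disease samples by default — sample counts typical of small clinical
microarray cohorts). Disease entries sit 3 observed reference standard
deviations above the per-gene reference maximum, plus a deviation of
0.75 s.d.: module genes share a latent factor giving target pairwise
correlation (default 0.9), background genes deviate independently. The
0.75 scale keeps entries outside the reference range (falling back
inside would take a 4-sigma draw), so the discriminant retains
essentially the whole planted signal; correlations are unaffected
because the per-gene transform is affine.

Calibration, measured with the generator itself over 100 seeds before
the recovery tests were frozen: minimum within-module similarity has
5th percentile ≈ 0.80 (worst 0.73); maximum background similarity has
95th percentile ≈ 0.60 (worst 0.69). The recovery tests therefore
threshold at τ = 0.7, between the two distributions.

What the generator does *not* emulate: array/batch effects, intensity-
dependent (MA-plot) noise, heavy-tailed expression, correlated
background structure, or down-regulation patterns. Passing the
planted-module tests shows the pipeline recovers block-correlated
abnormal expression under idealised Gaussian noise; it does not certify
performance on real microarray data, where preprocessing choices
dominate.

Random small games (uniform link sets, random Boolean supports) feed
the oracle suites; star/path/clique constructors pin the degree closed
forms ((center = 1/2 for any star; 3-path = (1/4, 1/2, 1/4)).

## Design choices that were genuinely open

- **Which matrix feeds the correlation.** The discriminant matrix is
  the default similarity source (it isolates disease-specific
  co-variation); raw disease-matrix correlation is available via
  `source: disease` since for real studies either is defensible.
- **Threshold default** τ = 0.9 in the pipeline config — a conservative
  value customary for hard-thresholded microarray co-expression
  networks; the five-gene demonstration uses 0.8 so that the network
  has interesting structure at n = 5.
- **Isolated genes** are kept in the universe (and score 0) rather than
  dropped, so score tables always cover the input gene list.
- **Empty-support arrays** count in the Shapley denominator. The
  alternative (renormalising over retained arrays) would inflate scores
  of studies with many all-normal arrays.

## Limitations

- The value function counts *entire* supports: a hub's influence is
  recognised only in subnetworks containing all its links. Scores on
  partial query networks are therefore conservative for high-degree
  genes.
- Correlation is computed on whatever columns the discriminant leaves;
  with very few disease samples the similarity estimates are noisy and
  hard thresholding is brittle (a known cost of signum adjacency).
- Weighted (soft-threshold) network games, player-based (Myerson)
  allocation, and alternative TU solution concepts are out of scope.
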