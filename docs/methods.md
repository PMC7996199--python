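# Methods

This note documents the models, conventions and numerical choices behind
`echonets`, in the order the pipeline applies them.

## Data model and preprocessing

A dataset is a flat table of posts (original / retweet / comment) with a
parent link, a topic label, a token list and three manual codes:
attitude (agree / disagree / query / unknown), information (seeking /
sharing / none) and civility (civil / uncivil). Original posts are coded
*agree* by convention — the author of a rebuttal endorses it. Timestamps
are ISO-8601 strings; since the format is uniform, lexicographic order is
chronological order, and input row order breaks remaining ties.

The low-impact filter removes originals whose cascades attracted fewer
than `min_count` (default 20) retweets **and** fewer than `min_count`
comments, together with every descendant post. Counting is over the full
cascade (what a platform's retweet counter displays), not direct children
only. The "either channel suffices" reading is the default because the
filter's purpose is to drop posts with low impact in *every* channel; the
stricter both-channels rule is available as `rule="both"`.

Retweeting and commenting are treated as separate populations: a user's
attitude in the comment network comes only from their comments. Users
visible only as targets are *agree* if they authored an original in the
topic and *unknown* otherwise. Inter-coder reliability is Cohen's κ with
the degenerate single-label case (p_e = 1) defined as 1.

## Sentiment scoring

Scoring is dictionary-based with graded intensities {1, 3, 5, 7, 9},
multiplicative adverb modifiers in (0, 2] and sign-flipping negations:

    value(term) = polarity · (−1)^n · (Π adverbs) · base
    score(text) = Σ over sentiment-word occurrences

Choices that the scheme leaves open, decided here:

- **Modifier scope** is the left context since the previous sentiment
  word, not crossing sentence-final punctuation. Trailing modifiers with
  no following sentiment word are discarded. This clause-bounded window
  is the conventional choice for dictionary scorers and is property-
  tested against an independent re-walk oracle.
- **Multiple adverbs multiply** (a "first adverb only" mode exists).
- **Adverb value 0 is excluded**: a zero multiplier would erase the term
  rather than attenuate it, so the valid range is open at 0.
- **No length normalization**: the score is a plain sum, so longer posts
  can reach larger magnitudes. Comparisons across groups are of the same
  post type, which keeps this fair.

## Networks and communities

User networks are directed and weighted (weight = interaction count);
self-interactions are dropped, since a self-edge has no homophily
reading. Community detection is Louvain modularity maximization
(networkx implementation, fixed seed, resolution 1.0 by default) on the
symmetrized weighted graph — modularity for directed graphs is not used,
matching the common practice of symmetrizing before partitioning.
Community ids are relabelled deterministically (decreasing size, then
smallest member id) so identical seeds give identical outputs.

Topology metrics use standard definitions — directed density, Newman
modularity of the given partition on the symmetrized graph, global
transitivity (3 × triangles / connected triples on the undirected simple
projection), reciprocity (fraction of directed edges whose reverse
exists). Metrics are *undefined*, reported as `None`/`NaN`, on graphs
that cannot support them (no edges, no connected triples, a single
node); they are never silently 0.

## Echo-chamber indices

- Edge classification: unclear if either endpoint is query/unknown,
  else like-minded iff the endpoints match. Symmetric by construction.
- Heterogeneity H = 1 − |A − D|/(A + D): the only form linear in the
  count balance that meets both anchor points (0 when one-sided, 1 when
  balanced); undefined when a community has no clear-attitude member.
- Community attitude score: (A − D)/(A + D + Q + U) by default — the
  mean member score with query/unknown counting 0. The clear-members-
  only variant (A − D)/(A + D) is available via
  `score_denominator="clear_only"`.
- Assortativity r: weighted Pearson correlation of (source score,
  target score) over directed inter-community edges, each edge counted
  with its weight. The networks are directed, so edges are used as-is by
  default; `mode="undirected"` symmetrizes by counting each edge in both
  orientations. Undefined when either endpoint-score sequence has zero
  variance. With unit weights the directed coefficient matches networkx's
  numeric assortativity, which serves as an independent cross-check in
  the tests.

Report tables round percentages to one decimal and r/H/modularity to
three, matching the precision conventional in this literature; the
underlying objects keep full precision.

## Statistical comparisons

ANOVA and chi-square delegate to scipy (`f_oneway`,
`chi2_contingency` without continuity correction). ANOVA on raw
sentiment values is the default, mirroring field practice despite
non-normality; the unit of analysis is the individual retweet/comment,
which inherits the edge type of its author → target pair. The
Mann-Whitney U test reports U of the first sample (pairs won + half the
ties; complete separation gives n_x·n_y) and uses exact enumeration over
group assignments when min(n) ≤ 8 and the assignment count is tractable
— the enumeration handles ties correctly, where textbook exact tables do
not — falling back to the tie-corrected normal approximation otherwise.
No multiple-testing correction is applied by default; Bonferroni and
Benjamini-Hochberg adjustments can be requested.

## Synthetic corpus generator

The generator emulates a multi-topic rebuttal corpus: per topic,
`n_original_posters` seed originals, `n_users` users with latent
attitudes drawn from a mixture (default 60% agree, 15% disagree, 10%
query, 15% unknown — an agreement-dominated regime typical of rebuttal
audiences), and Poisson event counts per user (defaults: 1.0 retweets,
0.5 comments).

Targeting implements a mixture design with like-minded preference
λ ∈ [0, 1]: with probability λ the event targets a uniformly chosen post
by a same-latent-attitude author; otherwise a uniformly chosen post.
**If the like-minded pool is empty the event is dropped** — selective
exposure taken literally: a user who finds no congenial content does not
engage. This makes λ = 1 produce *exactly* zero cross-cutting weight
(the property the tests pin down), while any λ < 1 lets minority
attitudes bootstrap their own content through the uniform branch. A
topic with no targetable posts at all raises a generation error naming
the topic.

Community structure is planted: users belong to latent blocks
(`community_count`, default 4) and prefer same-block targets within the
λ-selected pool (`within_community_pref`, default 0.85), giving Louvain
real modular signal; block attitudes are coupled to members
(`community_attitude_coupling`, default 0.8) so that high-λ runs produce
the attitude-homogeneous communities where echo chambers live. Setting
coupling and block preference to zero recovers the attitude-blind null
in which the clear-edge cross-cutting share has the closed form
2·q_A·q_D/(q_A + q_D)² — the calibration the tests check at λ = 0
(with a small upward like-minded bias from the all-agree originals,
which shrinks as events accumulate).

Post codes equal the latent attitude with 10% default noise (uniform
over the other three codes), so majority-vote aggregation is exercised
nontrivially. Tokens are sampled from the lexicon with a base
negative-word rate of 0.55 (interaction content in this domain skews
negative); cross-cutting events raise that rate by `sentiment_shift`
(default 0.25) — a mixture-weight change, never a score offset, so the
scorer remains the only route from tokens to scores. Information and
civility codes follow per-edge-type conditional probabilities with
cross-cutting defaults several times the like-minded ones (seeking
0.20 vs 0.05, sharing 0.12 vs 0.03, uncivil 0.15 vs 0.03), the
qualitative ordering reported for this kind of data.

What the generator does **not** emulate: real text (tokens are draws
from a toy lexicon), bursty temporal dynamics (timestamps are a uniform
clock), cross-topic user overlap, follower-graph exposure, or coder
disagreement structure. Passing tests therefore demonstrate that the
*measurement chain* is correct and sensitive to planted homophily — not
that any particular real platform exhibits these effects.

## Problem sizes and determinism

Tests run the generator at 40–250 users per topic for structural checks
and 1,200–1,500 users (≈2,000 events) for the λ = 0 calibration and
null-assortativity checks; type-I error calibration uses 200 replicates
of clean null draws (normal groups for ANOVA/Mann-Whitney, equal-rate
multinomials for chi-square) at α = 0.05 within two Monte-Carlo standard
errors. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the end-to-end pipeline writes byte-identical
outputs under identical config and seed, and the config hash embedded in
every report excludes only the output directory.

## Known limitations

- Louvain is a heuristic: partitions are deterministic per seed but not
  globally optimal, and the published modularity/assortativity values of
  any particular corpus are not exact targets for other datasets.
- The exact Mann-Whitney path enumerates up to ~2·10⁵ assignments;
  beyond that the asymptotic approximation is used even for min(n) ≤ 8.
- Aggregating a user who authored originals *and* interacted uses only
  the interaction posts for that mechanism's attitude.
- The sentiment scorer assumes tokenized input; segmentation of raw
  (e.g. Chinese) text is a plug-in concern outside the package.
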