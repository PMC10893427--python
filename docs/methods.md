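# Methods

This note records the model, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open — with the
reasoning behind each choice.

## Problem and model

Micro-activities are atomic actions located in short homogeneous sensor
windows (a table-tennis stroke, a "cut" step while cooking); macro-activities
are complete ordered sequences of them. Upstream systems (a micro-activity
classifier, or a dimensionality reduction such as a seeded UMAP over window
features) supply an $F$-dimensional embedding per window; `macrolink` decides,
online, whether the accumulated sequence is a complete macro-activity
(*graph validation*) and whether the next embedding may extend it (*link
prediction*).

A length-$T$ sequence is encoded as a directed star graph: all vertices point
at the last vertex $v_T$, which carries a self-loop; the adjacency is zero
except for a last column of ones, so exactly $T$ edges exist. Message passing
follows the printed edge orientation, which makes a single graph-attention
layer equivalent to attention of $v_T$ over all $T$ vertices. Vertices other
than $v_T$ have no in-edges and keep their projected self-features; Last
Vertex Pooling discards them, so only the $v_T$ row is computed on the fast
path.

**Positional encodings.** The star topology is permutation-invariant in rows
$1..T{-}1$, so temporal order must be restored in the features:
$\mathrm{PE}(t,f)=\cos(t/10000^{2f/F})$ for even $f$ and $\sin(\cdot)$ for odd
$f$, added element-wise. Two conventions are implemented exactly as the
architecture defines them, both deliberate departures from the classic
transformer table: cosine on even feature indices, and the raw feature index
$f$ (not the pair index $\lfloor f/2\rfloor$) in the exponent. The temporal
index is 1-based ($t\in\{1,\dots,T\}$); a 0-based switch exists for ablation.
PE is applied to graph vertices only, never to the candidate link embedding
$m_{T+1}$ (switchable).

**Heads.** The attention layer has $H=5$ heads and $2F$ output channels.
Head outputs are concatenated with per-head width $2F/H$ — integral for all
study dimensions $F\in\{5,15,25\}$; for indivisible widths the implementation
falls back to per-head width $2F$ with head averaging. Attention uses the
standard LeakyReLU(0.2) scoring with Glorot-uniform initialisation, seeded.
Whether dropout or normalisation layers were part of the original design is
unstated; none are used. Both heads are MLPs with $h=3$ hidden ReLU layers of
width $2F$ and a sigmoid output; the validator reads $E(G_T)$ (width $2F$),
the link predictor the concatenation with $m_{T+1}$ (width $3F$). Decisions
threshold the sigmoid at 0.5.

The network, reverse-mode gradients and Adam are implemented in-package on
numpy; gradients are verified against central finite differences in the test
suite. Equal-length graphs are batched as $(B,T,F)$ tensors and grouped by
length internally, which keeps desk-scale training in seconds.

## Grammar oracle

A grammar is the set of valid macro-activity sequences over a class alphabet,
indexed by a prefix trie. *Validity* is exact membership; *possibility* uses
prefix semantics across the whole grammar — a link is possible iff the
extended prefix is a prefix (proper or full) of *any* sequence — because
different macro-activities may share prefixes and a streaming consumer cannot
know which one is underway. The empty prefix means "start of a new sequence".
A prefix that equals a complete shorter macro-activity is both valid and
extendable; the pipeline's emit-and-continue case handles it without
special-casing here. Trie answers are property-tested against brute-force
scans.

The two shipped grammars mirror the structure of the study's real-data
derivations (7 cooking sequences of lengths 11, 11, 11, 9, 9, 9, 14 over 8
step classes; 55 table-tennis drills of lengths 1–10 over 8 stroke classes);
their concrete orderings are synthetic, generated once with a fixed seed and
frozen. The cooking grammar is prefix-free (no sequence is a proper prefix of
another), which makes the generator's counting identities exact: $R\cdot\sum_i
T_i = 30\cdot 74 = 2220$ samples, $R\cdot 7 = 210$ of them valid.

## Synthetic-data generator

The generator emulates the statistical shape of embeddings obtained from real
sensor windows without any sensor data:

* **Prototypes.** Per class $i$ a mean $\mu_i\in\mathbb R^F$; embeddings are
  drawn from the isotropic Gaussian $\mathcal N(\mu_i,\sigma)$ with a shared,
  pre-defined $\sigma$ (independent per-coordinate noise — the isotropic
  reading matches the circular spread the similarity analysis assumes).
  Prototypes can be fitted from windowed features through any pluggable
  reducer with `fit_transform` (a seeded UMAP in the real workflow; tests use
  deterministic linear projectors), or drawn at random with an optional
  minimum pairwise distance for controllable separability.
* **Similarity.** $s=\tfrac1{n^2}\sum_{i<j}\|\mu_i-\mu_j\|^{-1}$, with the
  $1/n^2$ normalisation exactly as defined (not $1/\binom n2$). Identical
  means raise an error naming the class pair.
* **Prefix embeddings.** Per sequence and repetition, one embedding is drawn
  per position and the $T$ prefix slices share those identical vectors — a
  prefix and its extensions are views of the same execution.
* **Labels.** Validator label = exact oracle validity of the class prefix.
  Possible links: one per successor class, label 1; within a repetition the
  own-sequence successor is that repetition's next drawn vector, other
  successor classes are drawn from the same split's pool (fresh Gaussian draw
  if a class is absent from a tiny split's pool). Impossible links: label 0,
  drawn uniformly from the same split's pool restricted to non-successor
  classes, with count

  $n_{\text{imp}} = \mathrm{round}(0.1\,n_{\text{total}})$ if $n_{\text{pos}}=0$, else $\bar n_{\text{pos}}$,

  where $n_{\text{total}}$ is the split's pool size, rounding is half-up, and
  $\bar n_{\text{pos}}$ is the rounded mean of $n_{\text{pos}}$ over the
  split's graphs with at least one successor (minimum 1). Restricting pools
  to the sample's own split prevents train/test leakage.
* **Split.** The $R=30$ repetitions of each sequence are split 60/20/20 with
  largest-remainder rounding; all prefixes of one repetition stay in one
  split, so no drawn vector appears in two splits (tested).

Study conditions default to $F\in\{5,15,25\}$, $\sigma\in\{0.05,0.15,0.25\}$,
$R=30$, seeds 1–3. What the generator does **not** emulate: real windows can
carry multiple overlapping micro-activities (which compresses class
separation), embedding clouds need not be isotropic or Gaussian, and class
frequencies in deployment are not balanced per sequence. Passing tests
therefore demonstrate the correctness of the machinery and the qualitative
behaviour of the model under controlled separability — not field performance
on raw signals.

## Training

Both heads use mean binary cross-entropy (probabilities clipped at $10^{-7}$);
the embedding block's loss is the unweighted sum. With backpropagation of the
summed loss the routing is automatic: each head lies on exactly one loss
path, so validator parameters receive only the validator gradient, link
parameters only the link gradient, and the shared encoder both (tested
directly). Tasks are trained jointly: each step consumes one batch per task
(batch 128), the shorter task stream simply ending earlier within an epoch.
Class balancing undersamples the majority class per task per epoch with a
fresh shuffle.

Early stopping monitors the **class-balanced** validation loss
$\text{loss}_V+\text{loss}_L$ — each class weighted to contribute one half
per task — with patience 10, maximum 500 epochs, restoring the
best-validation parameters. The balanced monitor is the deterministic
counterpart of the balanced training objective: with the heavy label
imbalance of generated datasets an unweighted monitor is dominated by the
majority class and can stop before minority-class structure (e.g.
order-ambiguous valid sequences) is learned. Divergence (non-finite loss)
aborts with a diagnostic. All randomness (prototypes, generation, shuffling,
initialisation) derives from explicit integer seeds; identical seeds give
identical histories.

## Streaming pipeline

With current sequence $M_T$ (the first stream item seeds it; no empty-sequence
model evaluation) and next embedding $m_{T+1}$, the validator decision $v$ and
link decision $l$ select one of four mutually exclusive cases: grow
($\lnot v\land l$), emit and restart with $m_{T+1}$ ($v\land\lnot l$), emit
and keep growing ($v\land l$), or archive the interrupted sequence and restart
($\lnot v\land\lnot l$). At stream end a terminal validator check emits or
archives the residual. Two underdetermined points were resolved as follows:
after a plain emit the new sequence starts with $m_{T+1}$ (mirroring the
interrupt case; without a reset the pipeline would stall), and the
emit-and-continue case does not suppress later emissions of a longer
completion — deduplication is the consumer's concern. The archive is
append-only within a run with an optional FIFO size bound; re-splicing
interrupted sequences back into the stream is deliberately out of scope.
Oracle-backed decision heads (exact grammar answers, class ids carried with
the stream) allow the control flow to be tested independently of learned
weights.

## Evaluation

Accuracy and macro F1 per task at threshold 0.5, computed with scikit-learn;
macro F1 averages the per-class F1 of classes 1 and 0 (under strong label
imbalance the unweighted class average is the informative reading), and a
class with neither true nor predicted members scores 0 (logged by the
degenerate-split warning path). Test sets keep their natural label
distribution by default. The sweep runs the full
$F\times\sigma\times\text{PE}\times\text{seed}$ grid, records per-seed
results and mean/std aggregates as tidy CSV, and continues past failed cells.

## Problem sizes used in tests and the acceptance script

Desk-scale conditions keep the full pipeline exact but small: the
oracle-equivalence experiment uses a 6-sequence grammar (lengths 3–6, 8
classes), $F=15$, $\sigma=0.01$ with prototype means at least $10\sigma$
apart, $R=10$, at most 100 epochs, 3 seeds; the positional-encoding ablation
uses $R=15$ and up to 250 epochs on a 4-sequence order-ambiguous grammar;
the noise comparison reuses the 6-sequence grammar at $\sigma\in\{0.05,
0.25\}$. These were chosen once as the smallest settings at which the
separability regime of the full study is preserved.

The ablation grammar pairs each valid sequence with an invalid permuted
counterpart that keeps the **same final vertex** (e.g. $[a,b,c]$ valid vs.
$[b,a,c]$, a prefix of $[b,a,c,d]$). This is the sharpest form of order
ambiguity for the star encoding: permutations that change the final vertex
also change the attention centre and are separable even without positional
encodings, whereas these pairs are provably indistinguishable without PE, so
the without-PE model is capped at chance on them.

## Known limitations

* The acceptance quantities are measured on synthetic Gaussian embeddings;
  absolute scores on real cooking/table-tennis signals depend on the upstream
  embedding quality and are outside what this package can reproduce.
* The generator's sample counts scale as $R\sum_i T_i$; dataset sizes in the
  hundreds of thousands require either large $R$ or an additional duplication
  scheme, which is intentionally not built in — `dataset_summary` exists to
  inspect any configuration's label distribution.
* Training is CPU-bound numpy; it is sized for grammars of tens of sequences,
  not for large-scale hyperparameter searches.
* Micro-activity windowing (change-point detection, adaptive windows) is an
  external prerequisite; the package consumes embeddings, not raw signals.
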