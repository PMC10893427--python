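# macrolink

Detection and validation of **macro-activities** — complete, ordered sequences
of micro-activities such as the strokes of a table-tennis drill or the steps
of a recipe — in streams of micro-activity embeddings from wearable inertial
sensors, via **graph link prediction**.

Sensor-based human activity recognition usually stops at window-level
micro-activity labels. `macrolink` addresses the layer above: given a stream
of per-window embedding vectors, decide *when a valid macro-activity has been
completed* and *whether the next micro-activity can extend the current
sequence*, without knowing macro-activity boundaries in advance.

## Method

A sequence $M_T = \{m_1,\dots,m_T\}$ of $F$-dimensional micro-activity
embeddings becomes a directed **star graph** $G_T=(V_T, A_T)$: vertex $v_t$
carries the embedding of $m_t$, and $A_T$ is zero except for its last column
($a_{[:,T]} = \mathbf{1}$), i.e. every vertex sends its single edge to the
last vertex $v_T$, which also has a self-loop. Because this topology erases
temporal order, vertex features are enriched with sinusoidal positional
encodings

$$\mathrm{PE}(t,f) = \begin{cases}\cos\!\big(t/10000^{2f/F}\big) & f \text{ even}\\ \sin\!\big(t/10000^{2f/F}\big) & f \text{ odd}\end{cases},\qquad V_T' = V_T \oplus \mathrm{PE},$$

with $t\in\{1,\dots,T\}$ the temporal vertex index. Three components operate
on $G_T$:

* **E** — a single graph-attention layer (5 heads, $2F$ channels) aggregates
  all vertices into $v_T$; *Last Vertex Pooling* extracts $E(G_T)$.
* **V** — the *graph validator*: 3 hidden ReLU layers of width $2F$ +
  sigmoid; decides whether $M_T$ is a complete macro-activity.
* **L** — the *link predictor*: reads $[E(G_T)\,\|\,m_{T+1}]$ through the
  same head shape; decides whether appending $m_{T+1}$ keeps the sequence a
  prefix of some macro-activity.

V and L are trained jointly (binary cross-entropy per head, the shared block
E on the summed loss; Adam, lr $10^{-3}$, batch 128, per-task class
balancing, early stopping with patience 10). A streaming state machine then
combines both decisions to segment a continuous embedding stream into
emitted macro-activities, continuing sequences, and archived interruptions.

Ground truth comes from a **grammar**: the set of valid micro-activity
sequences with a prefix-trie oracle for validity and link possibility. A
synthetic-data generator draws class-conditional isotropic Gaussian
embeddings $\mathcal N(\mu_i, \sigma)$ around per-class prototype means,
enumerates all prefix subsequences per execution, and labels everything
exactly via the oracle — so the learned model can be measured against exact
combinatorial truth.

## Worked example

```python
import numpy as np
import macrolink as ml

grammar = ml.Grammar.from_sequences(
    [f"c{i}" for i in range(8)],
    [[0, 1, 2], [0, 1, 3, 4], [2, 3, 4, 5],
     [5, 6, 7, 0, 1], [1, 2, 3, 4, 5], [6, 7, 0, 1, 2, 3]],
)
protos = ml.random_prototypes(8, F=15, sigma=0.01, seed=1, min_distance=0.1)
dataset = ml.generate_dataset(grammar, protos, ml.GeneratorConfig(repetitions=10, seed=1))
print(ml.dataset_summary(dataset))

est = ml.MacroActivityGNN(max_epochs=100, random_state=1).fit(dataset)
for task, m in ml.evaluate(est, dataset.test).items():
    print(task, f"accuracy={m.accuracy:.3f} macro_f1={m.macro_f1:.3f}")
```

prints

```
       graphs  valid  invalid  possible  impossible
split
train     162     36      126       138         702
val        54     12       42        46         102
test       54     12       42        46         102
validator accuracy=1.000 macro_f1=1.000
link accuracy=0.993 macro_f1=0.992
```

i.e. on well-separated embeddings ($\sigma=0.01$, prototype means at least
$10\sigma$ apart) the trained heads reproduce the grammar oracle on held-out
data: every complete macro-activity is recognised and >99% of candidate
links are classified correctly. The same model drives the stream segmenter:

```python
heads = ml.ModelHeads(est)
state, events = ml.run_stream(heads, [...])   # (embedding, class_id) items
```

The same workflow is available from the shell:

```bash
macrolink generate --grammar cooking.json --F 15 --sigma 0.15 --reps 30 --seed 1 --out data/
macrolink train --data data/ --seed 1 --out model.json
macrolink evaluate --model model.json --data data/
macrolink stream --model model.json --input embeddings.csv --out events.jsonl
```

Two example grammars ship with the package
(`ml.example_grammar("cooking")`: 7 recipes of lengths 11, 11, 11, 9, 9, 9,
14 over 8 preparation steps; `ml.example_grammar("table_tennis")`: 55 drills
of lengths 1–10 over 8 stroke classes).

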