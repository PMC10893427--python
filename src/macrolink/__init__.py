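"""macrolink: macro-activity detection and validation via graph link prediction.

Sequences of micro-activity embeddings (strokes, recipe steps) become directed
star graphs whose vertex features carry sinusoidal positional encodings; a
shared graph-attention encoder feeds two binary heads that decide whether the
sequence is a complete macro-activity and whether a candidate next
micro-activity can extend it.  A streaming state machine uses both decisions
to segment continuous micro-activity streams.  Class-conditional Gaussian
synthetic data with exact grammar-derived labels makes the whole approach
testable end to end.
"""

from importlib import resources

__version__ = "0.1.0"

from .grammar import (  # noqa: F401
    Grammar,
    MacroSequence,
    MicroActivityClass,
    enumerate_prefixes,
    is_possible_link,
    is_valid_macro,
    load_grammar,
    save_grammar,
    successors,
)
from .graphs import (  # noqa: F401
    MicroActivityGraph,
    StarGraphTransformer,
    apply_positional_encoding,
    build_graph,
    positional_encoding,
)
from .model import MacroActivityGNN, MacroActivityNetwork, last_vertex_pool  # noqa: F401
from .pipeline import ModelHeads, OracleHeads, mock_oracle_heads, run_stream, stream_step  # noqa: F401
from .synthdata import (  # noqa: F401
    GeneratorConfig,
    LabeledDataset,
    LabeledSample,
    LinkSample,
    PrototypeSet,
    dataset_summary,
    embedding_similarity,
    fit_class_prototypes,
    generate_dataset,
    generate_subsequence_embeddings,
    n_impossible,
    random_prototypes,
    sample_embedding,
)
from .training import TrainConfig, TrainHistory, multitask_loss, set_global_seed, train  # noqa: F401
from .evaluation import SweepConfig, TaskMetrics, evaluate, run_sweep  # noqa: F401


def example_grammar(name: str = "cooking") -> "Grammar":
    """Load one of the shipped example grammars ('cooking' or 'table_tennis')."""
    from .grammar import Grammar as _G
    import json

    path = resources.files("macrolink") / "data" / f"{name}.json"
    return _G.from_dict(json.loads(path.read_text()))
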