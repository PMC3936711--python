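import pytest

from casforge.io_model import Completeness
from casforge.synthetic_data import (
    emit_full_annotation_table,
    emit_hit_table,
    plant_cas_locus,
    simulate_replicon,
)


@pytest.fixture
def planted_replicon():
    """One complete-genome replicon with a II-A and an I-E locus planted."""
    genes, seqs, truth = simulate_replicon(
        60, seed=11, replicon_id="R0", completeness=Completeness.COMPLETE_GENOME
    )
    plant_cas_locus(genes, truth, "II-A", start_index=10, seed=11)
    plant_cas_locus(genes, truth, "I-E", start_index=30, seed=12)
    hits = emit_hit_table(truth, [g.protein_id for g in genes], fp_rate=0.0, seed=11)
    full_hits = emit_full_annotation_table(truth, seed=11)
    return genes, seqs, truth, hits, full_hits
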