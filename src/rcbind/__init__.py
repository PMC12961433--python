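"""rcbind: reverse-complement-aware sequence models of TF-DNA binding affinity.

Models relative binding affinities of fixed-length DNA reads (SELEX-seq
style tables), compares DNA-specific data-augmentation strategies with a
reverse-complement weight-sharing CNN and a self-attention regressor,
and interprets trained models at single-nucleotide resolution.
"""

from ._training import TrainingHistory
from .casestudy import (
    EnhancerScan,
    LogoCounts,
    ProbeAlignment,
    build_logos,
    cnn_align_probes,
    enhancer_importance,
    information_content,
    mutation_fold_change,
)
from .cnn import (
    CnnConfig,
    CnnModel,
    evaluate_strand_consistency,
    pairs_correlation,
    penalized_loss,
    r_squared,
    select_hyperparameters,
    train_cnn,
)
from .interpret import (
    ImportanceMatrix,
    consistency_score,
    consistency_study,
    deconvnet,
    gradient_times_input,
    ism,
    logo_projection,
    sliding_window_predictions,
)
from .mlr import AlignedDataset, RidgeModel, align_by_motif, mlr_predict, ridge_cv, ridge_fit
from .sa import SaConfig, SaModel, positional_encoding, self_attention, train_sa
from .selex import (
    AffinityRecord,
    AugmentationStrategy,
    GroundTruthAffinityModel,
    SelexDataset,
    SimConfig,
    augment,
    read_affinity_table,
    simulate_dataset,
    split_train_test,
    write_affinity_table,
)
from .seqcore import (
    count_yr_steps,
    find_motif_occurrences,
    one_hot,
    reverse_complement,
    yr_encode,
)

__version__ = "0.1.0"


def load_model(path):
    """Load any serialized model archive (CNN or SA) by its kind tag."""
    import json

    with open(path) as fh:
        kind = json.load(fh).get("kind")
    if kind == "cnn":
        return CnnModel.load(path)
    if kind == "sa":
        return SaModel.load(path)
    raise ValueError(f"unknown model archive kind {kind!r}")
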