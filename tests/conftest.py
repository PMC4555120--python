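import numpy as np
import pandas as pd
import pytest

from vkorcp.io_formats import AMINO_ACIDS, Alignment, SequenceRecord
from vkorcp.substitution import get_model
from vkorcp.synthetic_data import generate_study_bundle


@pytest.fixture(scope="session")
def wag():
    return get_model("WAG")


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic study bundle (60 taxa, 5 clades, planted
    invariant columns / marker / insertion / CP partner / toy bundle)."""
    return generate_study_bundle(seed=1)


@pytest.fixture(scope="session")
def inferred(bundle):
    """NJ tree with optimized branch lengths and estimated gamma shape for
    the bundle alignment (shared by conservation and acceptance tests)."""
    from vkorcp import phylo

    model = get_model("WAG", alpha=1.0)
    tree = phylo.nj_tree(phylo.ml_distance_matrix(bundle.alignment, model))
    tree = phylo.optimize_branch_lengths(tree, bundle.alignment, model, max_passes=2)
    alpha, _ = phylo.estimate_rate_params(bundle.alignment, tree, model)
    return tree, model.with_rates(alpha=alpha)


def random_alignment(n_taxa: int, n_sites: int, seed: int) -> Alignment:
    rng = np.random.default_rng(seed)
    return Alignment(
        [
            SequenceRecord(
                f"s{i:02d}", "".join(rng.choice(list(AMINO_ACIDS), n_sites))
            )
            for i in range(n_taxa)
        ]
    )


def additive_matrix(tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    tn = tree.taxon_namespace
    data = [
        [pdm.distance(tn.get_taxon(a), tn.get_taxon(b)) for b in labels]
        for a in labels
    ]
    return pd.DataFrame(data, index=labels, columns=labels)
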