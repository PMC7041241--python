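import numpy as np
import pytest

from famprof import OtuTable, TaxonAssignment

GENERA = [
    ("Xenorhabdus", "Morganellaceae"),
    ("Pseudomonas", "Pseudomonadaceae"),
    ("Alcaligenes", "Alcaligenaceae"),
    ("Stenotrophomonas", "Xanthomonadaceae"),
    ("Sphingomonas", "Sphingomonadaceae"),
    ("Serratia", "Yersiniaceae"),
]


def make_taxonomy(genus: str, family: str, genus_conf: float = 0.99) -> TaxonAssignment:
    return TaxonAssignment(
        ranks={
            "domain": "Bacteria", "phylum": "Proteobacteria",
            "class": "Gammaproteobacteria", "order": "Enterobacterales",
            "family": family, "genus": genus,
        },
        confidence={"genus": genus_conf},
    )


def random_table(
    rng: np.random.Generator,
    n_otus: int | None = None,
    n_samples: int | None = None,
    max_count: int = 50,
    marker: str = "other",
    ensure_positive_samples: bool = False,
) -> OtuTable:
    """Small random OTU table with random (valid) taxonomy."""
    n_otus = n_otus if n_otus is not None else int(rng.integers(1, 8))
    n_samples = n_samples if n_samples is not None else int(rng.integers(2, 6))
    counts = rng.integers(0, max_count, size=(n_otus, n_samples))
    if ensure_positive_samples:
        for j in range(n_samples):
            if counts[:, j].sum() == 0:
                counts[int(rng.integers(0, n_otus)), j] = 1
    otu_ids = [f"OTU_{i}" for i in range(n_otus)]
    taxonomy = {}
    for o in otu_ids:
        if rng.random() < 0.2:
            taxonomy[o] = TaxonAssignment.unassigned()
        else:
            genus, family = GENERA[int(rng.integers(0, len(GENERA)))]
            taxonomy[o] = make_taxonomy(genus, family,
                                        genus_conf=float(rng.uniform(0.5, 1.0)))
    return OtuTable(
        otu_ids=otu_ids,
        sample_ids=[f"S{j}" for j in range(n_samples)],
        counts=counts,
        taxonomy=taxonomy,
        marker=marker,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
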