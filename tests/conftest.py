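import numpy as np
import pytest

from sqamp.resources import ReferenceEntry, ReferenceResource, RefTree
from sqamp.synth import SynthConfig, simulate_dataset, simulate_reference

# peptides long enough to clear the homology filter's length floor
_PEP = ("MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKAL"
        "PDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE")


def _mutate_peptide(pep: str, positions: list[int], to: str = "A") -> str:
    out = list(pep)
    for p in positions:
        out[p] = to
    return "".join(out)


@pytest.fixture(scope="session")
def toy_resource():
    """Three-leaf star tree: two targets (A, B) and one decoy (C)."""
    seqs = {"A": _PEP, "B": _mutate_peptide(_PEP, [5, 40, 90]),
            "C": _mutate_peptide(_PEP, list(range(0, 120, 3)), "G")}
    entries = [ReferenceEntry(id=i, protein_seq=s,
                              label="target" if i in "AB" else "non_target",
                              taxonomy=("d__Bacteria",))
               for i, s in seqs.items()]
    tree = RefTree("(A:0.05,B:0.08,C:0.9);")
    return ReferenceResource(entries=entries, alignment=dict(seqs),
                             tree=tree, target_leaves={"A", "B"})


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_target_leaves=6, n_decoy_leaves=4,
                       protein_length=150, amplicon_start=61,
                       n_target_asvs=12, n_decoy_asvs=5)


@pytest.fixture(scope="session")
def small_reference(small_config):
    resource, _ = simulate_reference(small_config)
    return resource


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The package's default study conditions (seed 42, 1% error,
    50 target + 20 decoy ASVs)."""
    return simulate_dataset(SynthConfig())
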