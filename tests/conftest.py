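import numpy as np
import pytest

from orthocanon.io import SequenceRecord
from orthocanon.msa import MultipleAlignment
from orthocanon.simulate import SimulationConfig, generate_orthogroup


def make_record(acc, proteome, residues, canonical=False, reviewed=False, group=""):
    return SequenceRecord(
        accession=acc,
        proteome_id=proteome,
        entry_name=f"{acc}_{proteome}",
        review_status="reviewed" if reviewed else "unreviewed",
        is_canonical=canonical,
        gene_group_id=group or f"GC_{proteome}_{acc}",
        residues=residues,
    )


def random_msa(rng, n_rows=None, n_cols=None, gap_prob=0.3):
    """A random small MSA: first column residue-only so no pair degenerates."""
    n_rows = n_rows or int(rng.integers(2, 7))
    n_cols = n_cols or int(rng.integers(2, 40))
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
    probs = np.full(21, (1 - gap_prob) / 20)
    probs[-1] = gap_prob
    rows = []
    for i in range(n_rows):
        chars = rng.choice(letters, size=n_cols, p=probs)
        chars[0] = rng.choice(letters[:20])
        rows.append((f"S{i:02d}", "".join(chars)))
    # drop all-gap columns to satisfy the MSA invariant
    cols = [
        c for c in range(n_cols) if any(r[c] != "-" for _, r in rows)
    ]
    rows = [(lab, "".join(r[c] for c in cols)) for lab, r in rows]
    return MultipleAlignment("RAND", rows)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def planted_sim(rng):
    """One 6-proteome orthogroup with two decoy canonicals."""
    config = SimulationConfig(rng_seed=11, n_proteomes=6, decoy_fraction=0.3)
    return generate_orthogroup(
        config, np.random.default_rng(11), index=0,
        decoy_proteomes=["BOVIN", "MONDO"],
    )
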