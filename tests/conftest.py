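import collections
import logging

import numpy as np
import pytest

from tiratlas.formats_io import (
    AMINO_ACIDS,
    BACKGROUND_ARRAY,
    MultipleAlignment,
    ProteinDB,
    ProteinRecord,
    aligned_record,
    read_newick,
)

logging.getLogger("tiratlas").setLevel(logging.ERROR)


def random_sequence(rng, length):
    idx = rng.choice(20, size=length, p=BACKGROUND_ARRAY)
    return "".join(AMINO_ACIDS[i] for i in idx)


def mutate_fraction(rng, seq, frac):
    """Randomize a fixed fraction of positions (with replacement residues
    drawn uniformly, so some picks may silently match)."""
    chars = list(seq)
    idx = rng.choice(len(chars), int(frac * len(chars)), replace=False)
    for i in idx:
        chars[i] = AMINO_ACIDS[rng.integers(20)]
    return "".join(chars)


def random_binary_tree(rng, n, prefix="L", blmin=0.1, blmax=2.0):
    """Random rooted binary Newick tree over n leaves."""
    frags = [f"{prefix}{i:03d}" for i in range(n)]
    while len(frags) > 1:
        i = int(rng.integers(0, len(frags)))
        a = frags.pop(i)
        j = int(rng.integers(0, len(frags)))
        b = frags.pop(j)
        frags.append(
            f"({a}:{rng.uniform(blmin, blmax):.6f},"
            f"{b}:{rng.uniform(blmin, blmax):.6f})"
        )
    tree = read_newick(frags[0] + ";")
    tree.is_rooted = True
    return tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """One full desk-profile pipeline run, shared across tests."""
    from tiratlas.pipeline import desk_profile, run_pipeline

    outdir = tmp_path_factory.mktemp("desk_run")
    cfg = desk_profile(seed=1)
    result = run_pipeline(cfg, outdir)
    return cfg, result


@pytest.fixture(scope="session")
def desk_run_repeat(tmp_path_factory):
    """A second run of the same desk profile, for determinism checks."""
    from tiratlas.pipeline import desk_profile, run_pipeline

    outdir = tmp_path_factory.mktemp("desk_run_repeat")
    cfg = desk_profile(seed=1)
    result = run_pipeline(cfg, outdir)
    return cfg, result


def family_membership(truth):
    members = collections.defaultdict(set)
    for t in truth.non_decoys():
        members[t.clade].add(t.record_id)
    return dict(members)
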