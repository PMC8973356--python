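import pytest

from ysrna import (
    AbundanceModel,
    CleavageRuleSet,
    WT_DOTBRACKET,
    assign_reads,
    default_reference,
    default_windows,
    enumerate_variants,
    shifted_stem_dotbracket,
    simulate_pool,
    uniform_structures,
)
from ysrna.read_processing import process_reads


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def windows():
    return default_windows()


@pytest.fixture(scope="session")
def run_pool():
    """Simulate a pool and push it through trimming + assignment."""

    def _run(library, structures, rules=None, depth=10000, seed=1, **sim_kwargs):
        rules = rules if rules is not None else CleavageRuleSet()
        read_set = simulate_pool(
            library,
            structures,
            rules,
            sim_kwargs.pop("abundance", AbundanceModel()),
            depth=depth,
            seed=seed,
            **sim_kwargs,
        )
        accepted, report = process_reads((r.read_id, r.raw) for r in read_set.reads)
        table = assign_reads(accepted, library)
        return read_set, accepted, report, table

    return _run


@pytest.fixture(scope="session")
def l2_pool(reference, windows, run_pool):
    """Structure-neutral 3' pool (window in the single-stranded tail), default
    rules and wild-type structures; the canonical cleavage-competent pool."""
    lib = enumerate_variants(reference, windows["L2"])
    structs = uniform_structures(lib, WT_DOTBRACKET)
    read_set, accepted, report, table = run_pool(lib, structs, depth=10000, seed=11)
    return lib, structs, read_set, accepted, report, table


@pytest.fixture(scope="session")
def l1_shifted_pool(reference, windows, run_pool):
    """Stem-window pool under imposed structures with stem S3 moved 2 nt
    upstream (start 50): the longer-fragment scenario."""
    lib = enumerate_variants(reference, windows["L1"])
    db = shifted_stem_dotbracket(reference, WT_DOTBRACKET, 2)
    structs = uniform_structures(lib, db)
    read_set, accepted, report, table = run_pool(lib, structs, depth=10000, seed=12)
    return lib, structs, read_set, accepted, report, table


@pytest.fixture(scope="session")
def l3_pool(reference, windows, run_pool):
    """RO60-proximal 3' pool under the wild-type structure: only variants
    keeping the G:C anchor pair are 3'-cleavage competent."""
    lib = enumerate_variants(reference, windows["L3"])
    structs = uniform_structures(lib, WT_DOTBRACKET)
    read_set, accepted, report, table = run_pool(lib, structs, depth=10000, seed=14)
    return lib, structs, read_set, accepted, report, table


@pytest.fixture(scope="session")
def l4_pool(reference, windows, run_pool):
    """Motif-window pool: only the wild-type UGGGU motif passes the 5' rule."""
    lib = enumerate_variants(reference, windows["L4"])
    structs = uniform_structures(lib, WT_DOTBRACKET)
    read_set, accepted, report, table = run_pool(lib, structs, depth=20000, seed=13)
    return lib, structs, read_set, accepted, report, table
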