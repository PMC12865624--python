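import pytest

import vnarkit as vk


def run_pipeline(library):
    """Translate, dedupe, annotate and classify a synthetic library."""
    records = [vk.translate_and_qc(c) for c in vk.library_to_clones(library)]
    usable = [r for r in records if r.aa is not None and r.is_complete_insert]
    unique, mult = vk.dedupe_sequences(usable)
    maps = vk.annotate_repertoire(unique)
    calls, excluded = vk.classify_repertoire(maps, unique)
    return records, unique, maps, calls, excluded


@pytest.fixture(scope="session")
def small_library():
    """Defect-free 500-clone library with the published type composition."""
    return vk.generate_library(vk.fig3a_spec(n_clones=500, seed=11))


@pytest.fixture(scope="session")
def small_pipeline(small_library):
    return run_pipeline(small_library)
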