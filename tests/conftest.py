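import functools

import pytest

from erleak.io_cli import run_scenario


@pytest.fixture(scope="session")
def metrics_for():
    """Memoized end-to-end pipeline runs shared across tests."""

    @functools.lru_cache(maxsize=None)
    def _run(name, seed, n_cells):
        return run_scenario(name, seed=seed, n_cells=n_cells)

    return _run
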