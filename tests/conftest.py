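import numpy as np
import pytest

from meaprior import (ElectrodeGrid, PipelineConfig, generate_network,
                      render_image, run_pipeline, simulate_spikes)


@pytest.fixture(scope="session")
def demo():
    """One deterministic end-to-end run on a 16x16 culture.

    Shared by integration, classification and pipeline tests; the network,
    image, spike trains and full pipeline result are all derived from
    seed 0.
    """
    grid = ElectrodeGrid(n_rows=16, n_cols=16)
    net = generate_network(n_neurons=100, grid=grid, seed=0)
    img = render_image(net, noise_level=0.05, seed=0)
    trains = simulate_spikes(net, T=300.0, seed=0)
    cfg = PipelineConfig(n_rows=16, n_cols=16, seed=0)
    res = run_pipeline(cfg, img, trains, net.neuron_map(), classify=False)
    return {"grid": grid, "net": net, "img": img, "trains": trains,
            "cfg": cfg, "res": res}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def poisson_train(rng, rate, T, row=0, col=0):
    from meaprior import SpikeTrain
    k = rng.poisson(rate * T)
    return SpikeTrain(row, col, np.sort(rng.uniform(0.0, T, size=k)), T)
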