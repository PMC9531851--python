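import numpy as np
import pytest

from cosimloop.demo import MPCConfig, make_demo_system


@pytest.fixture(scope="session")
def demo_system():
    """The default generated plant (seed 0), scaled to the rat setpoint."""
    return make_demo_system(0)


@pytest.fixture(scope="session")
def mpc_config():
    return MPCConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mediator_server(tmp_path_factory):
    """A live mediator on an ephemeral localhost port, shared per session."""
    from cosimloop.mediator import MediatorApp, serve_background

    app = MediatorApp(tmp_path_factory.mktemp("mediator_store"),
                      apikeys={"xyz", "abc"})
    server, url = serve_background(app)
    yield app, url
    server.shutdown()
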