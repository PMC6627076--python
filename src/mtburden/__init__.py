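"""mtburden: somatic mtDNA mutation burden and heteroplasmy dynamics with age."""

from importlib import resources as _resources

from .burden import *  # noqa: F401,F403
from .burden import __all__ as _all

__version__ = "0.1.0"


def default_config_path():
    """Path to the bundled reference configuration (JSON)."""
    return _resources.files(__package__) / "default_config.json"


__all__ = list(_all) + ["default_config_path", "__version__"]
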