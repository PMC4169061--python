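"""Helpers shared by the numbered drivers."""

import importlib.util
from pathlib import Path


def load_config():
    """Load 00_config.py (its name is not a valid module identifier)."""
    path = Path(__file__).parent / "00_config.py"
    spec = importlib.util.spec_from_file_location("analysis_config", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod
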