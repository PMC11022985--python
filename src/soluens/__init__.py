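"""soluens: deep-ensemble recurrent networks for aqueous solubility prediction."""

__version__ = "0.1.0"

from .chem import canonicalize, enumerate_randomized, from_selfies, to_selfies  # noqa: E402,F401
from .network import EnsemblePrediction, MemberPrediction, aggregate  # noqa: E402,F401
from .training import nll_loss  # noqa: E402,F401

__all__ = [
    "__version__",
    "canonicalize",
    "enumerate_randomized",
    "to_selfies",
    "from_selfies",
    "aggregate",
    "nll_loss",
    "MemberPrediction",
    "EnsemblePrediction",
    "DeepEnsembleRegressor",
    "SelfiesTokenizer",
]


def __getattr__(name):
    # estimators pull in sklearn; import lazily to keep light imports fast
    if name in ("DeepEnsembleRegressor", "SelfiesTokenizer"):
        from . import estimators

        return getattr(estimators, name)
    raise AttributeError(f"module 'soluens' has no attribute {name!r}")
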