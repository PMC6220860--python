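"""Minimal estimator base compatible with scikit-learn's parameter protocol.

Implemented locally so the runtime package has no scikit-learn dependency;
the interface (``get_params`` / ``set_params`` driven by ``__init__``
keywords) is what sklearn model-selection utilities rely on.
"""

from __future__ import annotations

import inspect

from .exceptions import ConfigurationError


class BaseEstimator:
    @classmethod
    def _get_param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return sorted(
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind != p.VAR_KEYWORD
        )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._get_param_names()}

    def set_params(self, **params):
        valid = set(self._get_param_names())
        for key, value in params.items():
            if key not in valid:
                raise ConfigurationError(
                    f"Invalid parameter {key!r} for estimator {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"


def check_fitted(estimator, attribute: str) -> None:
    if not hasattr(estimator, attribute):
        raise ConfigurationError(
            f"{type(estimator).__name__} is not fitted yet; call fit() first"
        )
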