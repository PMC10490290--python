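import numpy as np
import pytest

from appledet._nn import Parameter, Module


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def walk_parameter_arrays(module: Module):
    """Independent parameter oracle: flatten the attribute tree and collect
    every Parameter array, without using Module.num_parameters()."""
    seen = []

    def visit(obj):
        if isinstance(obj, Parameter):
            seen.append(obj.data)
            return
        if isinstance(obj, Module):
            for v in vars(obj).values():
                visit(v)
        elif isinstance(obj, (list, tuple)):
            for v in obj:
                visit(v)

    visit(module)
    return seen


def count_parameters_oracle(module: Module) -> int:
    return sum(int(a.size) for a in walk_parameter_arrays(module))
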