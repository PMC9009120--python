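import pytest

from hallmarknet import load_taxonomy
from hallmarknet.synthetic import make_ard_dictionary


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def ard_dictionary():
    return make_ard_dictionary(20)


@pytest.fixture()
def write_tsv(tmp_path):
    """Write tab-joined rows to a temp file and return its path."""

    def _write(name, rows):
        path = tmp_path / name
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n", encoding="utf-8")
        return path

    return _write
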