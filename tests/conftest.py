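import pytest

from simmeta import (
    assemble_directory,
    build_term_index,
    generate_md_study,
    load_catalog,
    load_packaged_dictionaries,
)


@pytest.fixture(scope="session")
def dictionaries():
    return load_packaged_dictionaries()


@pytest.fixture(scope="session")
def term_index(dictionaries):
    return build_term_index(dictionaries)


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def md_manifest(tmp_path_factory):
    root = tmp_path_factory.mktemp("md-study")
    return generate_md_study(root / "study", seed=1)


@pytest.fixture(scope="session")
def md_experiment(md_manifest):
    return assemble_directory(md_manifest.directory)
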