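import pytest

import srdialog as sd


@pytest.fixture(scope="session")
def spec():
    return sd.urolithiasis_template()


@pytest.fixture(scope="session")
def lex():
    return sd.default_lexicon()


@pytest.fixture(scope="session")
def rules():
    return sd.default_rules()


@pytest.fixture(scope="session")
def advice_mappings():
    return sd.default_advice_mappings()


@pytest.fixture(scope="session")
def verbalizations():
    return sd.default_verbalizations()


@pytest.fixture(scope="session")
def triggers():
    return sd.default_trigger_set("en")


@pytest.fixture()
def blank(spec):
    return sd.empty_state(spec)


def toy_template_doc(n_fields=6):
    """A small coded template: n always-required yes/no fields."""
    return {
        "template_id": "toy",
        "schema_version": 1,
        "locale": "en",
        "sections": [{"section_id": "organ", "label": "right kidney"}],
        "fields": [
            {
                "field_id": f"f{i}",
                "section_id": "organ",
                "label": f"Field {i}",
                "value_kind": "coded",
                "allowed_codes": ["RID13173", "RID28453"],
                "triggers": {
                    "RID28453": {"affirmed": "RID28453", "negated": "RID13173"}
                },
                "normal_value": "RID13173",
            }
            for i in range(n_fields)
        ],
    }


@pytest.fixture()
def toy_spec():
    return sd.load_template(toy_template_doc())
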