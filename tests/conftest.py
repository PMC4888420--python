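import pytest

from odmannotate import (AnnotationSignature, DataItem, DataModel, FormDef,
                         ItemGroup, build_index, make_table1_fixture,
                         make_toy_vocabulary)


@pytest.fixture()
def toy_vocab():
    return make_toy_vocabulary()


@pytest.fixture()
def table1_corpus():
    return make_table1_fixture()


@pytest.fixture()
def table1_index(table1_corpus):
    return build_index(table1_corpus)


def small_model(model_id="M1", item_names=("Height",), annotations=(None,),
                form_name="Vital Signs"):
    """One-form model with one item per name, optionally pre-annotated."""
    items, refs = [], []
    for i, (name, ann) in enumerate(zip(item_names, annotations), 1):
        oid = f"IT.{i}"
        signature = AnnotationSignature.parse(ann) if ann else None
        items.append(DataItem(oid=oid, name=name, data_type="text",
                              annotation=signature))
        refs.append(oid)
    return DataModel(
        model_id=model_id, study_name=f"Study {model_id}",
        forms=[FormDef("F.1", form_name, ["IG.1"])],
        groups=[ItemGroup("IG.1", "Group", refs)],
        items=items,
    )
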