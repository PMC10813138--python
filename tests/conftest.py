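import pytest

from cypmatch.name_resolution import NameIndex


@pytest.fixture
def small_index() -> NameIndex:
    """Toy canonical vocabulary used across resolution tests."""
    return NameIndex(
        atc_to_name={
            "C09AA05": "ramipril",
            "C03AA03": "hydrochlorothiazide",
            "N02BB02": "metamizole",
        },
        name_set={"metoprolol", "tilidine", "acetylsalicylic acid"},
    )


@pytest.fixture
def medication_csv(tmp_path):
    """Minimal medication table with a combination product and an empty name."""
    path = tmp_path / "meds.csv"
    path.write_text(
        "case_id,name,atc\n"
        "c1,Hydrochlorothiazid/Ramipril,C09BA05\n"
        "c1,Metamizol 500mg,N02BB02\n"
        "c2,Metoprololtartrat,\n"
        "c2,,\n"
        "c3,Tilidin,\n",
        encoding="utf-8",
    )
    return path
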