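"""Small three-generation pedigree builder used by k=2 tests."""

from sibphase.pedigree import Individual, Pedigree


def three_generation_pedigree(n_children: int = 3) -> Pedigree:
    inds = [
        Individual("GF1", sex="male"),
        Individual("GM1", sex="female"),
        Individual("GF2", sex="male"),
        Individual("GM2", sex="female"),
        Individual("F", "GF1", "GM1", sex="male"),
        Individual("M", "GF2", "GM2", sex="female"),
    ]
    for j in range(n_children):
        inds.append(Individual(f"C{j}", "F", "M"))
    return Pedigree(inds)
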