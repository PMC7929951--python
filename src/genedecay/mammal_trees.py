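"""Bundled order-level mammalian topologies and gene-loss states.

Small dated trees transcribed from the comparative literature on PCSK9
loss in placental mammals: the four recently advocated arrangements of
the Laurasiatheria orders (with Eulipotyphla expanded to family level and
Cetartiodactyla to sub-clade level), the two competing Eulipotyphla
family arrangements, and dated chronograms for Cetartiodactyla and
Chiroptera used to bracket loss-event ages.  Node ages are in My before
present; within-topology ages not pinned by a published split date are
plausible interpolations — the loss counts depend only on the topologies
and the published dates named below:

* Whippomorpha–Ruminantia split ~70 My, Ruminantia crown ~52 My;
* crown Noctilionoidea (Phyllostomidae+Mormoopidae+Noctilionidae) ~49 My.
"""

from __future__ import annotations

from importlib import resources

from .loss_phylogenetics import Chronogram

__all__ = [
    "laurasiatheria_topologies",
    "laurasiatheria_states",
    "eulipotyphla_topologies",
    "eulipotyphla_states",
    "cetartiodactyla_chronogram",
    "cetartiodactyla_states",
    "chiroptera_chronogram",
    "PER_CLADE_LOSS_RANGES",
]

# Independent-loss ranges per affected Laurasiatheria clade, as argued
# from the lesion evidence: Eulipotyphla 2 or 3 (depending on family
# arrangement), Ruminantia 1, Carnivora 1, Pholidota 1, Chiroptera 1
# (single early loss favoured; independent losses per clade formally
# possible), Perissodactyla 1 to 3 (per-family losses suggested).
PER_CLADE_LOSS_RANGES: dict[str, tuple[int, int]] = {
    "Eulipotyphla": (2, 3),
    "Ruminantia": (1, 1),
    "Carnivora": (1, 1),
    "Pholidota": (1, 1),
    "Chiroptera": (1, 1),
    "Perissodactyla": (1, 3),
}


def _read(name: str) -> str:
    return (
        resources.files("genedecay.data") / name
    ).read_text()


def laurasiatheria_topologies() -> dict[str, Chronogram]:
    """The four alternative Laurasiatheria arrangements, keyed a-d."""
    return {
        key: Chronogram.from_newick(
            _read(f"laurasiatheria_topology_{key}.nwk")
        )
        for key in "abcd"
    }


def laurasiatheria_states() -> dict[str, str]:
    states = {}
    for line in _read("laurasiatheria_states.tsv").splitlines():
        if line.strip():
            tip, st = line.split("\t")
            states[tip] = st
    return states


def eulipotyphla_topologies() -> dict[str, Chronogram]:
    """Family-level Eulipotyphla under the two advocated arrangements."""
    return {
        "solenodontidae_basal": Chronogram.from_newick(
            _read("eulipotyphla_solenodontidae_basal.nwk")
        ),
        "talpidae_soricidae_sisters": Chronogram.from_newick(
            _read("eulipotyphla_talpidae_soricidae.nwk")
        ),
    }


def eulipotyphla_states() -> dict[str, str]:
    return {
        "Solenodontidae": "lost",
        "Talpidae": "retained",
        "Soricidae": "lost",
        "Erinaceidae": "lost",
    }


def cetartiodactyla_chronogram() -> Chronogram:
    return Chronogram.from_newick(_read("cetartiodactyla_chronogram.nwk"))


def cetartiodactyla_states() -> dict[str, str]:
    return {
        "Hippopotamidae": "retained",
        "Cetacea": "retained",
        "Pecora": "lost",
        "Tragulidae": "lost",
        "Suidae": "retained",
        "Camelidae": "retained",
    }


def chiroptera_chronogram() -> Chronogram:
    return Chronogram.from_newick(_read("chiroptera_chronogram.nwk"))
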