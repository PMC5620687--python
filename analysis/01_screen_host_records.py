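"""Screen pre-introduction host records for taxonomic overlap with the endemic moth.

Could an assessor, using only the host lists published before each parasitoid
reached Hawaii, have flagged the endemic crambid moth Udea stellata as a
potential non-target host?  The answer differs sharply by agent: the native-
range host list of Cotesia marginiventris already contains a congeneric
species (Udea rubigalis, the celery leaf-tier), the strongest possible
pre-introduction warning, while the Meteorus laphygmae list holds only
noctuids and one pierid — no overlap at any level.  Trathala flavoorbitalis
had no native-range records at all before its detection; its Hawaii host list
is summarized for context.

Writes results/host_screening.json.
"""

import json
from collections import Counter
from pathlib import Path

from biopra import builtin_dataset, taxonomic_overlap_flag

OUT = Path(__file__).resolve().parents[1] / "results"

NONTARGET = {"family": "Crambidae", "genus": "Udea"}


def main() -> None:
    screening = {}
    for agent, fixture in [
        ("cmarginiventris", "hosts_cmarginiventris_native"),
        ("mlaphygmae", "hosts_mlaphygmae_native"),
    ]:
        hosts = builtin_dataset(fixture)
        report = taxonomic_overlap_flag(hosts, NONTARGET["family"], NONTARGET["genus"])
        screening[agent] = {
            "host_records": len(hosts),
            "families": sorted({h.family for h in hosts}),
            "overlap_level": report.level,
            "matching_species": [h.species for h in report.matches],
        }
        print(f"{agent}: {len(hosts)} pre-introduction host records, "
              f"overlap with {NONTARGET['genus']} ({NONTARGET['family']}): {report.level}")

    hawaii = builtin_dataset("hosts_tflavoorbitalis_hawaii")
    fam_counts = Counter(h.family for h in hawaii)
    screening["tflavoorbitalis"] = {
        "note": "no native-range records predate the Hawaii detection; "
                "Hawaii host list shown for context",
        "hawaii_host_records": len(hawaii),
        "hawaii_family_counts": dict(sorted(fam_counts.items())),
        "hawaii_udea_species": sorted(
            h.species for h in hawaii if h.genus == "Udea"
        ),
    }
    print(f"tflavoorbitalis: no pre-introduction records; Hawaii list has "
          f"{len(hawaii)} hosts incl. {fam_counts['Crambidae']} crambids, "
          f"{len(screening['tflavoorbitalis']['hawaii_udea_species'])} Udea spp.")

    OUT.mkdir(exist_ok=True)
    (OUT / "host_screening.json").write_text(
        json.dumps(screening, indent=2) + "\n", encoding="utf-8"
    )
    print(f"wrote {OUT / 'host_screening.json'}")


if __name__ == "__main__":
    main()
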