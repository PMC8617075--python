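#!/usr/bin/env python
"""Generate the study site table: one TAG-like fixture plus a batch of
synthetic vents spanning slow/intermediate/fast-spreading source ranges.

Writes results/sites.csv in the layout consumed by the plume stage.
"""

from pathlib import Path

from ventplume.synthetic_sites import (
    SiteTemplate,
    generate_site,
    tag_like_site,
    write_site_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921


def main():
    OUT.mkdir(exist_ok=True)
    sites = [tag_like_site()]
    for regime, base in (("slow", 0), ("intermediate", 100), ("fast", 200)):
        template = SiteTemplate(regime=regime, seed=SEED)
        sites += [
            generate_site(template, seed=SEED + base + i,
                          name=f"{regime}_{i}")
            for i in range(3)
        ]
    write_site_table(sites, OUT / "sites.csv")
    print(f"wrote {len(sites)} sites to {OUT / 'sites.csv'}")
    for s in sites:
        print(f"  {s.name}: T0={s.source.T0:.0f}C u0={s.source.u0:.2f}m/s "
              f"d={2 * s.source.r0:.3f}m depth={s.source.depth:.0f}m")


if __name__ == "__main__":
    main()
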