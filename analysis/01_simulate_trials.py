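"""Generate the in-silico experiment: three 150-plot trials with known
genetic ground truth, rendered to georeferenced 1.5 cm/pixel mosaics,
plus noisy visual senescence scores.

Writes layouts (GeoJSON), mosaics and latent class rasters (GeoTIFF),
training regions, ground truth and scores (CSV) under scratch/.
"""

import json

from trial_config import CONFIG
from uavpheno.pipeline import run_pipeline


def main() -> None:
    report = run_pipeline(CONFIG, stages=["simulate"])
    info = report["stages"]["simulate"]
    print(f"simulated {len(info['trials'])} trials, "
          f"{info['n_plots']} plots total, in {info['seconds']} s")
    print(json.dumps(info, indent=1))


if __name__ == "__main__":
    main()
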