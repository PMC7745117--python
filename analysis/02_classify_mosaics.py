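"""Train per-class color signatures from the training polygons and run
maximum-likelihood classification on every trial mosaic, then score the
maps against the generator's latent class rasters.

With the default well-separated color models the maps should be nearly
perfect — this stage is where real-world performance would degrade first
if class spectra overlapped.
"""

from trial_config import CONFIG, SCRATCH

from uavpheno import evaluate_classification
from uavpheno import io as pio
from uavpheno.pipeline import run_pipeline


def main() -> None:
    report = run_pipeline(CONFIG, stages=["classify"])
    print(f"classified {report['stages']['classify']['pixels_classified']:,}"
          " pixels")
    for trial in report["stages"]["classify"]["trials"]:
        classified = pio.read_labels(SCRATCH / f"classified_{trial}.tif")
        latent = pio.read_labels(SCRATCH / f"latent_{trial}.tif")
        _, acc, recalls = evaluate_classification(classified, latent)
        rec = ", ".join(f"{k} {v:.4f}" for k, v in recalls.items())
        print(f"{trial}: overall accuracy {acc:.5f}  recall: {rec}")


if __name__ == "__main__":
    main()
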