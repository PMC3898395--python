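"""Regenerate the shipped CSV fixtures under fixtures/.

Both use the default device and the reference measurement design
(71 drain voltages x glucose {0,2,4,6,8,10,20,50} mM at 1 mg/mL buffer):

* iv_noise_free.csv       — no noise (generator seed 0, draws all zero)
* iv_noise_1pct_seed1.csv — 1% multiplicative Gaussian noise, seed 1
"""

from pathlib import Path

from glucofet import NoiseModel, generate_experiment, write_iv_csv

FIXTURES = Path(__file__).resolve().parent.parent / "fixtures"


def main() -> None:
    FIXTURES.mkdir(exist_ok=True)
    write_iv_csv(
        generate_experiment(noise=NoiseModel(0.0, 0.0, 0)),
        FIXTURES / "iv_noise_free.csv",
    )
    write_iv_csv(
        generate_experiment(noise=NoiseModel(0.01, 0.0, 1)),
        FIXTURES / "iv_noise_1pct_seed1.csv",
    )
    print(f"wrote fixtures to {FIXTURES}")


if __name__ == "__main__":
    main()
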