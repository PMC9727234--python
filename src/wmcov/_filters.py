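"""Hard-coded orthogonal wavelet filter banks.

Coefficients are the standard published Daubechies/symlet decomposition and
reconstruction filters (float64, full precision). Symlets are the
near-symmetric variant of the Daubechies family.
"""

FILTER_BANKS = {
    "haar": {
        "dec_lo": [0.7071067811865476, 0.7071067811865476],
        "dec_hi": [-0.7071067811865476, 0.7071067811865476],
        "rec_lo": [0.7071067811865476, 0.7071067811865476],
        "rec_hi": [0.7071067811865476, -0.7071067811865476],
    },
    "db2": {
        "dec_lo": [-0.12940952255126037, 0.2241438680420134, 0.8365163037378079, 0.48296291314453416],
        "dec_hi": [-0.48296291314453416, 0.8365163037378079, -0.2241438680420134, -0.12940952255126037],
        "rec_lo": [0.48296291314453416, 0.8365163037378079, 0.2241438680420134, -0.12940952255126037],
        "rec_hi": [-0.12940952255126037, -0.2241438680420134, 0.8365163037378079, -0.48296291314453416],
    },
    "db4": {
        "dec_lo": [-0.010597401785069032, 0.0328830116668852, 0.030841381835560764, -0.18703481171909309, -0.027983769416859854, 0.6308807679298589, 0.7148465705529157, 0.2303778133088965],
        "dec_hi": [-0.2303778133088965, 0.7148465705529157, -0.6308807679298589, -0.027983769416859854, 0.18703481171909309, 0.030841381835560764, -0.0328830116668852, -0.010597401785069032],
        "rec_lo": [0.2303778133088965, 0.7148465705529157, 0.6308807679298589, -0.027983769416859854, -0.18703481171909309, 0.030841381835560764, 0.0328830116668852, -0.010597401785069032],
        "rec_hi": [-0.010597401785069032, -0.0328830116668852, 0.030841381835560764, 0.18703481171909309, -0.027983769416859854, -0.6308807679298589, 0.7148465705529157, -0.2303778133088965],
    },
    "sym2": {
        "dec_lo": [-0.12940952255092145, 0.22414386804185735, 0.836516303737469, 0.48296291314469025],
        "dec_hi": [-0.48296291314469025, 0.836516303737469, -0.22414386804185735, -0.12940952255092145],
        "rec_lo": [0.48296291314469025, 0.836516303737469, 0.22414386804185735, -0.12940952255092145],
        "rec_hi": [-0.12940952255092145, -0.22414386804185735, 0.836516303737469, -0.48296291314469025],
    },
    "sym4": {
        "dec_lo": [-0.07576571478927333, -0.02963552764599851, 0.49761866763201545, 0.8037387518059161, 0.29785779560527736, -0.09921954357684722, -0.012603967262037833, 0.0322231006040427],
        "dec_hi": [-0.0322231006040427, -0.012603967262037833, 0.09921954357684722, 0.29785779560527736, -0.8037387518059161, 0.49761866763201545, 0.02963552764599851, -0.07576571478927333],
        "rec_lo": [0.0322231006040427, -0.012603967262037833, -0.09921954357684722, 0.29785779560527736, 0.8037387518059161, 0.49761866763201545, -0.02963552764599851, -0.07576571478927333],
        "rec_hi": [-0.07576571478927333, 0.02963552764599851, 0.49761866763201545, -0.8037387518059161, 0.29785779560527736, 0.09921954357684722, -0.012603967262037833, -0.0322231006040427],
    },
    "sym5": {
        "dec_lo": [0.027333068345077982, 0.029519490925774643, -0.039134249302383094, 0.1993975339773936, 0.7234076904024206, 0.6339789634582119, 0.01660210576452232, -0.17532808990845047, -0.021101834024758855, 0.019538882735286728],
        "dec_hi": [-0.019538882735286728, -0.021101834024758855, 0.17532808990845047, 0.01660210576452232, -0.6339789634582119, 0.7234076904024206, -0.1993975339773936, -0.039134249302383094, -0.029519490925774643, 0.027333068345077982],
        "rec_lo": [0.019538882735286728, -0.021101834024758855, -0.17532808990845047, 0.01660210576452232, 0.6339789634582119, 0.7234076904024206, 0.1993975339773936, -0.039134249302383094, 0.029519490925774643, 0.027333068345077982],
        "rec_hi": [0.027333068345077982, -0.029519490925774643, -0.039134249302383094, -0.1993975339773936, 0.7234076904024206, -0.6339789634582119, 0.01660210576452232, 0.17532808990845047, -0.021101834024758855, -0.019538882735286728],
    },
    "sym6": {
        "dec_lo": [0.015404109327027373, 0.0034907120842174702, -0.11799011114819057, -0.048311742585633, 0.4910559419267466, 0.787641141030194, 0.3379294217276218, -0.07263752278646252, -0.021060292512300564, 0.04472490177066578, 0.0017677118642428036, -0.007800708325034148],
        "dec_hi": [0.007800708325034148, 0.0017677118642428036, -0.04472490177066578, -0.021060292512300564, 0.07263752278646252, 0.3379294217276218, -0.787641141030194, 0.4910559419267466, 0.048311742585633, -0.11799011114819057, -0.0034907120842174702, 0.015404109327027373],
        "rec_lo": [-0.007800708325034148, 0.0017677118642428036, 0.04472490177066578, -0.021060292512300564, -0.07263752278646252, 0.3379294217276218, 0.787641141030194, 0.4910559419267466, -0.048311742585633, -0.11799011114819057, 0.0034907120842174702, 0.015404109327027373],
        "rec_hi": [0.015404109327027373, -0.0034907120842174702, -0.11799011114819057, 0.048311742585633, 0.4910559419267466, -0.787641141030194, 0.3379294217276218, 0.07263752278646252, -0.021060292512300564, -0.04472490177066578, 0.0017677118642428036, 0.007800708325034148],
    },
    "sym8": {
        "dec_lo": [-0.0033824159510061256, -0.0005421323317911481, 0.03169508781149298, 0.007607487324917605, -0.1432942383508097, -0.061273359067658524, 0.4813596512583722, 0.7771857517005235, 0.3644418948353314, -0.05194583810770904, -0.027219029917056003, 0.049137179673607506, 0.003808752013890615, -0.01495225833704823, -0.0003029205147213668, 0.0018899503327594609],
        "dec_hi": [-0.0018899503327594609, -0.0003029205147213668, 0.01495225833704823, 0.003808752013890615, -0.049137179673607506, -0.027219029917056003, 0.05194583810770904, 0.3644418948353314, -0.7771857517005235, 0.4813596512583722, 0.061273359067658524, -0.1432942383508097, -0.007607487324917605, 0.03169508781149298, 0.0005421323317911481, -0.0033824159510061256],
        "rec_lo": [0.0018899503327594609, -0.0003029205147213668, -0.01495225833704823, 0.003808752013890615, 0.049137179673607506, -0.027219029917056003, -0.05194583810770904, 0.3644418948353314, 0.7771857517005235, 0.4813596512583722, -0.061273359067658524, -0.1432942383508097, 0.007607487324917605, 0.03169508781149298, -0.0005421323317911481, -0.0033824159510061256],
        "rec_hi": [-0.0033824159510061256, 0.0005421323317911481, 0.03169508781149298, -0.007607487324917605, -0.1432942383508097, 0.061273359067658524, 0.4813596512583722, -0.7771857517005235, 0.3644418948353314, 0.05194583810770904, -0.027219029917056003, -0.049137179673607506, 0.003808752013890615, 0.01495225833704823, -0.0003029205147213668, -0.0018899503327594609],
    },
}
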