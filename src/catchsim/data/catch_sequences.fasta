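>Q11 n_term_acetylated=true c_term_amidated=true
QQKFQFQFEQQ
>CATCH(2+) n_term_acetylated=true c_term_amidated=true
QQQFKFKFQQQ
>CATCH(2-) n_term_acetylated=true c_term_amidated=true
QQQFEFEFQQQ
>CATCH(4+) n_term_acetylated=true c_term_amidated=true
QQKFKFKFKQQ
>CATCH(4-) n_term_acetylated=true c_term_amidated=true
QQEFEFEFEQQ
>CATCH(6+) n_term_acetylated=true c_term_amidated=true
KQKFKFKFKQK
>CATCH(6-) n_term_acetylated=true c_term_amidated=true
EQEFEFEFEQE
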