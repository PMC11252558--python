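/root/pkg/teststest_connectivity.pytest_network.pytest_stats.pytest_prediction.pytest_acceptance.pyconftest.pytest_preprocess.pytest_hhse.pytest_pipeline.pytest_synthetic.pytest_edfio.py      �   �������
�?,�f��         �   ����N^��+�;�,�f��          �   �����>d��R,�f��         �   `���5l�#�,�f��          �   .�������31
�,�f��         �   �������P�O	,�f��         �   ����P�/��"��,�f��                                          �   ���>�\8�:L�,�f��         �   R����jU=��a�,�f��         �   #���N</�IUG,�f��         �   ������B��ɨ,�f��          !a	�yS b	G!a	�yS b	G������� �   ��������      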