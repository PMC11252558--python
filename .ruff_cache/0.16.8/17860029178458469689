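/root/pkg/teststest_connectivity.pytest_network.pytest_hhse.pytest_prediction.pytest_acceptance.pyconftest.pytest_preprocess.pytest_stats.pytest_pipeline.pytest_synthetic.pytest_edfio.py      �   �������
�?��f��         �   �������.�D���f��         �   �����>d��R��f��         �   _����jU=��a���f��         �   -�������31
ޭ�f��         �   �������P�O	��f��         �   �����%�/�����f��                                         �   ~���>�\8�:L㭸f��         �   R����v��譸f��         �   #���N</�IUG��f��         �   �����%�/�����f��         !b	�yS a	G!b	�yS a	G������� �   ��������      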